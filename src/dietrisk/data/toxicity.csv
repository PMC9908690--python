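contaminant_id,rfd_mg_per_kg_day,sf_per_mg_kg_day,source
Hg,1.0e-4,,EPA IRIS methylmercury chronic oral RfD
Cd,1.0e-3,,EPA IRIS cadmium (food) chronic oral RfD
Cu,4.0e-2,,EPA HEAST copper oral reference value
Al,1.0,,EPA PPRTV aluminum chronic oral reference value
Pb,3.5e-3,,JECFA-derived provisional tolerable intake for lead (no EPA RfD exists)
Se,5.0e-3,,EPA IRIS selenium chronic oral RfD
Ba,2.0e-1,,EPA IRIS barium chronic oral RfD
Sn,6.0e-1,,EPA HEAST tin oral reference value
Mo,5.0e-3,,EPA IRIS molybdenum chronic oral RfD
Ni,2.0e-2,,EPA IRIS nickel soluble salts chronic oral RfD
Cr,1.5,,EPA IRIS chromium(III) insoluble salts chronic oral RfD
PCB 153,,2.0,EPA IRIS polychlorinated biphenyls upper-bound oral slope factor (high risk and persistence)
PBB 153,,8.90,EPA IRIS polybrominated biphenyls oral slope factor
"p,p'-DDE",,0.34,EPA IRIS DDE oral slope factor
"p,p'-DDT",5.0e-4,0.34,EPA IRIS DDT chronic oral RfD and slope factor
PBDE 47,1.0e-4,,EPA IRIS BDE-47 chronic oral RfD
PBDE 99,1.0e-4,,EPA IRIS BDE-99 chronic oral RfD
PBDE 100,1.0e-4,,EPA IRIS BDE-100 chronic oral RfD
PBDE 153,2.0e-4,,EPA IRIS BDE-153 chronic oral RfD
mirex,2.0e-4,,EPA IRIS mirex chronic oral RfD
oxychlordane,5.0e-4,0.35,EPA IRIS chlordane (technical) RfD and slope factor applied to the oxidation product
cis-nonachlor,5.0e-4,0.35,EPA IRIS chlordane (technical) values applied to the nonachlor constituent
trans-nonachlor,5.0e-4,0.35,EPA IRIS chlordane (technical) values applied to the nonachlor constituent
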