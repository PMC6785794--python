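# Cross-dose S factors for bone marrow from the low- and high-uptake
# compartments, Gy per MBq*h in the source region, for 177Lu photon
# emissions.  These are stated approximations: mass-weighted means over
# reference adult organ masses using published specific-absorbed-fraction
# compilations, rounded to two significant figures.  Site-specific tables
# can replace this file via the run configuration.

[meta]
version = "bmdosim-sfactors-2026.1"
radionuclide = "Lu-177"

[female]
s_bm_from_low_gy_per_mbq_h = 5.0e-9
s_bm_from_high_gy_per_mbq_h = 2.0e-8
provenance = "mass-weighted photon SAF estimate, adult female reference organ masses"

[male]
s_bm_from_low_gy_per_mbq_h = 4.5e-9
s_bm_from_high_gy_per_mbq_h = 1.8e-8
provenance = "mass-weighted photon SAF estimate, adult male reference organ masses"
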