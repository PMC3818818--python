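# nfkbcoupling model parameters
# rates per minute, abundances in a.u., delays in minutes
tau_traf1_min = 120.0
tau_nfkb2_min = 90.0
ikk_act_rate = 2.0
ikk_inact_rate = 0.02
txn_max_ikba = 1.2
txn_max_traf1 = 0.1243
txn_max_p100 = 0.13433
txn_max_canon_reporter = 1.5
txn_max_tnip1 = 0.5
txn_fb_p100 = 1425.41
txn_fb_traf1 = 217.76
hill_K_rela = 0.3
hill_K_p52 = 0.66
hill_K_p52_traf1 = 3.08
hill_h = 4.0
tln_rate_ikba = 1.0
tln_rate_traf1 = 0.4
tln_rate_p100 = 9.941
deg_mrna = 1.0
deg_ikba = 0.05
deg_traf1 = 0.4
deg_p100 = 3.5033
deg_p52 = 0.2136
nik_synth_rate = 1.0
nik_fast_deg = 1.0
nik_stable_deg = 1.0
traf1_nik_bind = 0.02
proc_rate = 1.0
proc_K = 0.02467
ikba_rela_assoc = 2.0
ikba_deg_by_ikk = 2.0
rela_total = 1.0
basal_txn = 1e-06
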