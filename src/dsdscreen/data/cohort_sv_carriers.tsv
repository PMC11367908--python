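# Candidate-SV carrier table for the 32 affected cohort individuals.
# Constructed to satisfy the published marginals simultaneously: 22 single-SV
# carriers (14 WWOX-only, 4 PITX1-only, 2 SHC1-only, 2 chr3-SV-only), 10
# multi-SV carriers; WWOX 20/32, PITX1 10/32, chr3 SV 7/32, SOX9 6/32,
# WNT6 2/32 (always alongside WWOX or the chr3 SV), SHC1 2/32.  The
# individual multi-SV combinations beyond these marginals are synthetic.
individual_id	svs
d001	wwox_del
d002	wwox_del
d003	wwox_del
d004	wwox_del
d005	wwox_del
d006	wwox_del
d007	wwox_del
d008	wwox_del
d009	wwox_del
d010	wwox_del
d011	wwox_del
d012	wwox_del
d013	wwox_del
d014	wwox_del
d015	pitx1_del
d016	pitx1_del
d017	pitx1_del
d018	pitx1_del
d019	shc1_dup
d020	shc1_dup
d021	chr3_del
d022	chr3_del
d023	wwox_del;pitx1_del
d024	wwox_del;pitx1_del
d025	wwox_del;pitx1_del
d026	wwox_del;pitx1_del
d027	wwox_del;pitx1_del;sox9_dup
d028	wwox_del;pitx1_del;chr3_del;sox9_dup
d029	chr3_del;sox9_dup
d030	chr3_del;sox9_dup
d031	chr3_del;sox9_dup;wnt6_del
d032	chr3_del;sox9_dup;wnt6_del
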