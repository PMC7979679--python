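id,name,length_cm,D0_prox_cm,D0_dist_cm,c0_prox_m_s,c0_dist_m_s,b,gamma,Gamma_visc,parent_id,n_elements
1,aortic_root,4.0,2.9,2.7,6.2,6.3,2.0,9.0,4.9,-1,4
2,brachiocephalic,3.5000000000000004,1.3,1.2,7.0,7.3,2.0,9.0,2.2,1,4
3,right_common_carotid,17.0,0.75,0.65,8.0,9.0,2.0,9.0,1.27,2,12
4,right_brachial,44.0,0.75,0.55,8.5,10.0,2.0,9.0,1.27,2,24
5,aortic_arch_a,2.5,2.6,2.5,6.3,6.4,2.0,9.0,4.4,1,3
6,left_common_carotid,19.0,0.75,0.65,8.0,9.0,2.0,9.0,1.27,5,12
7,aortic_arch_b,3.5000000000000004,2.5,2.3000000000000003,6.4,6.6,2.0,9.0,4.23,5,4
8,left_brachial,44.0,0.75,0.55,8.5,10.0,2.0,9.0,1.27,7,24
9,thoracic_aorta,23.75,2.3000000000000003,2.0,6.6,7.2,2.0,9.0,3.89,7,16
10,celiac,6.0,1.2,1.1,8.5,9.0,2.0,9.0,2.03,9,6
11,abdominal_aorta,13.0,1.9,1.7000000000000002,7.2,7.8,2.0,9.0,3.21,9,20
12,left_iliac,14.000000000000002,1.25,1.0,8.5,9.5,2.0,9.0,2.11,11,10
13,right_iliac,14.000000000000002,1.25,1.0,8.5,9.5,2.0,9.0,2.11,11,10
14,left_internal_iliac,8.0,0.7,0.6,10.0,10.5,2.0,9.0,1.18,12,6
15,left_femoral,42.9,0.8500000000000001,0.65,10.0,11.5,2.0,9.0,1.44,12,24
16,right_internal_iliac,8.0,0.7,0.6,10.0,10.5,2.0,9.0,1.18,13,6
17,right_femoral,42.9,0.8500000000000001,0.65,10.0,11.5,2.0,9.0,1.44,13,24
18,left_cerebral,12.0,0.35,0.3,10.5,11.0,2.0,9.0,0.59,6,8
19,left_external_carotid,8.0,0.45000000000000007,0.4,10.0,10.5,2.0,9.0,0.76,6,6
20,right_cerebral,12.0,0.35,0.3,10.5,11.0,2.0,9.0,0.59,3,8
21,right_external_carotid,8.0,0.45000000000000007,0.4,10.0,10.5,2.0,9.0,0.76,3,6
22,left_radial,24.0,0.35,0.3,11.0,12.0,2.0,9.0,0.59,8,12
23,left_ulnar,24.0,0.4,0.35,11.0,12.0,2.0,9.0,0.68,8,12
24,right_radial,24.0,0.35,0.3,11.0,12.0,2.0,9.0,0.59,4,12
25,right_ulnar,24.0,0.4,0.35,11.0,12.0,2.0,9.0,0.68,4,12
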