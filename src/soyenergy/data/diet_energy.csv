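experiment,diet,sample_id,dfi_kg_d,cp_pct_dm,de,me,men,me_de,men_de
1,RD,,1.559,18.36,3873,3787,3695,97.8,95.4
1,TD,1,1.550,22.99,4133,4072,3974,98.5,96.2
1,TD,2,1.555,23.66,4127,4055,3953,98.3,95.8
2,RD,,1.636,18.56,3819,3738,3656,97.9,95.7
2,TD,3,1.585,25.26,4085,4017,3910,98.3,95.7
3,RD,,1.708,16.75,3857,3758,3683,97.4,95.5
3,TD,4,1.747,22.97,4060,3968,3875,97.8,95.5
4,RD,,1.751,17.61,3897,3787,3702,97.2,95.0
4,TD,5,1.768,23.27,4074,3995,3908,98.1,95.9
4,TD,6,1.779,23.62,4121,4020,3931,97.5,95.4
5,RD,,1.820,18.39,3890,3780,3701,97.2,95.2
5,TD,7,1.819,24.35,4052,3943,3863,97.3,95.3
6,RD,,1.557,17.55,3880,3821,3730,98.5,96.1
6,TD,8,1.555,24.02,4117,4065,3963,98.7,96.2
7,RD,,1.650,18.83,3908,3815,3727,97.6,95.4
7,TD,9,1.638,24.43,4032,3936,3856,97.6,95.6
8,RD,,1.749,17.78,3868,3785,3700,97.9,95.7
8,TD,10,1.716,23.82,4019,3937,3838,97.9,95.5
9,RD,,1.832,18.15,3859,3760,3681,97.4,95.4
9,TD,11,1.862,24.90,4091,3985,3890,97.4,95.1
9,TD,12,1.819,24.83,4103,3965,3868,96.6,94.3
9,TD,13,1.842,24.86,4129,3963,3881,96.0,94.0
10,RD,,1.753,20.22,3846,3738,3647,97.2,94.8
10,TD,14,1.793,25.36,3969,3840,3750,96.7,94.5
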