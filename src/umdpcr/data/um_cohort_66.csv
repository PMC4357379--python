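tumour_id,snp_chr3,dpcr_chr3,karyotype_chr3,snp_8q,dpcr_8q,snp_8p,dpcr_8p,karyotype_chr8,reference_flagged
99-184,1.5,1.4,0,3.3,4.4,2.5,2.5,0,0
99-187,2.0,2.2,0,2.0,2.2,1.9,2.4,0,0
99-239,1.4,0.9,1,3.3,3.5,2.3,1.9,2,0
20-005,1.4,1.2,0,2.9,3.3,1.3,1.1,0,0
20-042,1.5,1.6,1,3.1,3.9,1.8,1.7,2,0
20-125,2.0,2.2,0,2.7,3.2,1.9,1.9,0,0
20-128,1.5,1.5,1,3.9,6.2,2.0,2.0,2,0
20-173,1.3,1.3,1,2.3,2.5,1.7,1.6,2,0
20-178,1.3,1.1,0,4.2,6.0,2.1,2.2,0,0
01-042,2.0,2.1,0,1.9,1.9,2.0,2.0,0,0
01-074,1.9,2.2,0,2.7,3.5,2.3,2.4,0,0
01-091,1.4,1.2,0,3.8,4.6,2.1,2.0,0,0
01-129,1.8,1.8,,2.1,2.2,2.2,2.1,,0
01-131,1.5,1.5,,3.4,4.6,1.4,1.3,,0
02-158,2.0,2.3,0,2.0,2.2,2.0,2.2,0,0
02-167,1.6,1.5,,2.1,2.1,2.0,2.0,,0
02-174,1.4,1.1,0,2.6,2.7,2.7,2.8,0,0
02-189,1.4,1.2,1,2.3,2.4,1.8,1.6,2,0
02-199,1.8,2.0,1,1.9,2.0,2.0,2.2,0,0
03-031,1.4,1.3,1,3.9,4.6,1.4,1.3,2,0
03-086,2.0,2.2,0,1.9,2.0,2.1,2.2,0,0
03-087,2.1,1.7,0,2.0,1.6,2.0,1.6,0,1
03-120,2.0,2.0,,1.9,1.9,1.9,2.0,,0
03-129,1.5,1.4,0,2.7,3.1,1.9,2.1,0,0
04-018,1.9,2.0,0,2.3,2.7,2.4,2.6,0,0
04-035,1.3,1.1,1,2.7,3.0,1.2,1.0,2,0
04-074,2.0,1.9,,2.0,2.0,2.0,1.9,,0
04-075,1.9,2.0,0,2.9,3.0,1.9,2.1,0,0
04-103,2.0,1.9,0,2.0,1.9,2.1,2.0,0,0
04-112,1.3,1.1,1,3.5,3.5,2.0,1.8,2,0
05-005,1.3,1.4,0,3.2,3.1,2.0,1.8,0,0
05-020,1.9,1.9,,4.5,4.6,2.0,1.8,,0
05-033,1.1,1.2,1,2.1,2.4,1.9,1.9,2,0
05-034,1.5,1.6,1,3.1,3.1,3.0,2.8,1,0
05-046,1.1,1.1,1,3.7,3.5,1.9,1.8,2,0
05-058,2.0,1.9,0,1.9,1.9,2.1,1.8,0,0
05-061,1.0,1.1,,5.7,5.8,3.4,3.5,,0
06-004,1.1,1.1,,4.2,3.8,1.1,1.0,,0
06-008,1.2,1.4,1,2.9,3.0,2.0,2.0,0,0
06-009,1.1,1.0,1,3.2,3.0,2.0,3.0,1,0
06-010,2.0,2.0,,2.0,2.0,1.3,1.2,,0
06-011,2.0,2.1,,3.2,3.5,2.5,2.3,,0
06-014,1.6,1.8,0,4.5,4.7,1.6,1.7,1,0
06-015,1.0,1.2,1,3.9,3.8,1.3,1.3,2,0
06-023,1.3,1.4,1,2.6,2.5,2.3,2.0,2,0
06-033,2.1,2.1,0,3.2,3.0,2.8,2.8,1,0
06-036,2.0,2.2,0,3.1,2.9,2.9,2.9,1,0
06-038,1.1,1.1,0,3.4,3.3,1.2,1.1,0,0
06-041,1.2,1.3,1,4.7,4.6,1.3,1.1,2,0
06-042,1.1,1.3,1,3.0,2.9,1.0,1.1,2,0
06-045,1.5,1.6,,3.8,4.1,1.5,1.4,,0
06-046,1.9,1.7,,2.7,2.3,2.0,1.6,,1
06-047,1.2,1.4,0,2.8,2.7,1.3,1.2,0,0
07-003,2.0,2.2,,1.9,2.2,2.1,2.1,,0
07-004,2.1,2.1,0,2.0,2.0,2.0,2.0,0,0
07-005,1.3,1.3,1,3.9,4.2,1.2,1.2,2,0
07-007,1.0,1.1,0,1.9,1.9,2.0,2.1,0,0
07-012,1.5,1.7,,3.7,3.8,2.0,1.9,,0
07-030,1.1,1.2,1,3.2,3.5,1.3,1.3,2,0
07-034,1.9,2.0,0,2.0,2.1,2.1,2.1,0,0
07-047,1.0,1.1,1,2.0,2.0,2.1,1.9,0,0
07-050,1.1,1.2,1,4.9,4.9,2.9,3.1,2,0
08-004,1.2,1.2,,2.8,2.8,2.1,1.9,,0
08-005,1.3,1.2,1,5.7,7.0,1.8,1.8,2,0
08-008,1.1,1.2,0,2.7,2.9,2.0,2.1,0,0
08-029,1.2,1.3,0,3.2,3.5,2.1,2.1,0,0
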