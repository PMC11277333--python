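# Deep-learning + docking screening stage: the 19 candidate compounds that
# passed BC >= 0.99, RG >= 9 (pKa scale) and docking energy <= -7 kcal/mol.
compound_id,bc,rg,docking
L102-0385,0.9988,9.1991,-8.4419
8601-0106,1.0000,9.1074,-8.0588
5795-0108,1.0000,9.3339,-7.9719
C684-0025,0.9985,9.0321,-7.9543
4290-0112,0.9959,9.0631,-7.8938
V008-1080,0.9983,9.3616,-7.7966
C200-6885,0.9975,9.0352,-7.5277
C163-0038,1.0000,9.4493,-7.4668
V014-8131,1.0000,9.1249,-7.4660
E208-0020,1.0000,9.1201,-7.4659
S431-0991,0.9999,9.1192,-7.4172
C163-0087,1.0000,9.0191,-7.3098
V001-2119,0.9947,9.0161,-7.2953
G744-0225,0.9996,9.0588,-7.2909
SA50-0140,1.0000,9.1702,-7.2194
C163-0039,1.0000,9.4007,-7.1913
5025-0002,0.9999,9.0076,-7.1717
7238-1541,0.9986,9.1096,-7.1709
M769-1095,0.9936,9.0299,-7.1306
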