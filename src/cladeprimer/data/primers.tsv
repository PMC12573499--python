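name	spec	orientation	adaptor	note
BM0639-5LNA	GTTAAAAAGCTCGTAGTTGAA+TTT	forward	ACACTCTTTCCCTACACGACGCTCTTCCGATCT	basal-Mucoromycota-specific forward, V4 region
BM0853-3LNA	CAACT+ATCCCTATTMATCATTAC	reverse	GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT	basal-Mucoromycota-specific reverse, V4 region
AM-Sal-F	AAGCTCGTAGTTGAATTT	forward		published AMF forward reference
AMDGR	CCCAACTATCCCTATTAATCAT	reverse		published AMF reverse reference
Fun18S1-LNA	CCATGCATGT+CTAAGTAT+AA	forward		universal fungal forward
EF3	TCCTCTAAATGACCAAGTTTG	reverse		universal fungal reverse
NS1	GTAGTCATATGCTTGTCTC	forward		universal forward
EF3-plant	TCCTCTAAATGATAAGGTTCA	reverse		plant-adapted universal reverse
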