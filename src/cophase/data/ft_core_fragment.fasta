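>FT_promoter_CORE_fragment
TATTTCCAGTGTATTAGTGTGGTGGGTTTGGAATACCACAAACAGAAATAAAAAGAAAGA
AAAATATGAAATAAGACGACAATGTGTGATGTACGTAGAATCAGTTTTAGATTCTAGTAC
ATCAATAGACAAGAAAAAGATTGTGGTTATGATTTCACCGACCCGAGTT
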