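date,predicted,actual
2024-01,276.56,277
2024-02,181.56,182
2024-03,420.56,421
2024-04,592.56,593
2024-05,844.56,845
2024-06,1280.55,1281
2024-07,2847.56,2848
2024-08,3834.56,3484
2024-09,1738.56,1739
2024-10,1107.56,1108
2024-11,682.56,683
2024-12,543.56,544
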