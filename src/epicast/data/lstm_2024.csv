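date,predicted,actual
2024-01,300.35,227
2024-02,258.13,182
2024-03,323.40,421
2024-04,520.96,593
2024-05,896.40,845
2024-06,1470.41,1281
2024-07,2129.49,2848
2024-08,2302.45,3484
2024-09,1765.14,1739
2024-10,1168.87,1108
2024-11,718.35,683
2024-12,445.62,544
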