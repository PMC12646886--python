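date,predicted
2025-01,214.62
2025-02,260.84
2025-03,462.92
2025-04,590.92
2025-05,800.88
2025-06,965.11
2025-07,2410.36
2025-08,2651.36
2025-09,1711.15
2025-10,941.22
2025-11,628.21
2025-12,465.05
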