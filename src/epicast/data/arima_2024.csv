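date,predicted,actual,lcl95,ucl95
2024-01,231.81,277,-1217.18,1680.80
2024-02,274.95,182,-1901.10,2451.00
2024-03,470.81,421,-2061.32,3002.94
2024-04,594.76,593,-2080.54,3270.06
2024-05,802.44,845,-1919.01,3523.89
2024-06,965.57,1281,-1767.05,3698.19
2024-07,2410.42,2848,-323.88,5144.72
2024-08,2651.36,3484,-83.00,5385.73
2024-09,1711.24,1739,-1023.16,4445.64
2024-10,841.42,1108,-1793.07,3675.92
2024-11,628.51,683,-2106.06,3363.08
2024-12,465.42,544,-2269.19,3200.02
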