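{
  "comment": "Critical values of the Nalimov outlier statistic q at 95% confidence, by sample size n; the statistic is bounded by sqrt(n-1) and the critical values approach 1.96 for large n.",
  "0.05": {
    "3": 1.409,
    "4": 1.645,
    "5": 1.757,
    "6": 1.814,
    "7": 1.848,
    "8": 1.870,
    "9": 1.885,
    "10": 1.895,
    "12": 1.911,
    "15": 1.923,
    "20": 1.936,
    "30": 1.946,
    "inf": 1.960
  }
}
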