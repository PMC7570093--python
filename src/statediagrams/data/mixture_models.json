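{
  "_comment": "Published solute-composition mixture models (Scheffe, no intercept) with their ANOVA summaries. The E model's XM coefficient appears truncated in the printed source (an orphan '-0.0003' with no variable; transcribed here as the XM linear coefficient) and its XF coefficient 0.946 is inconsistent with the measured pure-fructose E of 0.0954 (likely a lost leading zero); the E model is therefore unsuitable for quantitative use.",
  "tgs": {
    "terms": {
      "XF": 8.31, "XG": 29.98, "XS": 58.68, "XP": 1295.36, "XA": -885.31, "XM": 10.52,
      "XFXP": -2139.92, "XFXA": 1653.18, "XGXP": -2555.95, "XGXA": 2109.04,
      "XGXM": 122.3, "XSXP": -3002.49, "XSXA": 2526.09, "XSXM": 468.11
    },
    "anova": {"p_value": "<0.0001", "r_squared": 0.983, "sd": 6.22, "cv_percent": 11.86}
  },
  "k": {
    "terms": {
      "XF": 2.9, "XG": 3.76, "XS": 4.48, "XP": -130.1, "XA": 119.4, "XM": 3.59,
      "XFXP": 109.55, "XFXA": -106.31, "XGXP": 72.36, "XGXA": -67.19, "XGXM": 12.55,
      "XSXM": 28.65, "XPXA": 119.8, "XPXM": 249.97, "XAXM": -248.14
    },
    "anova": {"p_value": "<0.0001", "r_squared": 0.984, "sd": 0.31, "cv_percent": 6.42}
  },
  "e": {
    "terms": {
      "XF": 0.946, "XG": 0.1019, "XS": 0.0617, "XP": 0.0543, "XA": 0.0648, "XM": -0.0003,
      "XFXP": -0.1471, "XSXM": -0.0719
    },
    "anova": {"p_value": "<0.0001", "r_squared": 0.94, "sd": 0.00682, "cv_percent": 10.61}
  },
  "b": {
    "terms": {
      "XF": 0.1413, "XG": 0.0645, "XS": 0.0956, "XP": -9.0225, "XA": 3.9767, "XM": -0.0164,
      "XFXP": 8.3373, "XGXP": 8.0965, "XSXP": 7.8839, "XSXM": 1.0128,
      "XPXM": 14.3016, "XAXM": -9.8217
    },
    "anova": {"p_value": 0.0018, "r_squared": 0.833, "sd": 0.04, "cv_percent": 23.25}
  },
  "tg_prime": {
    "terms": {
      "XF": -55.95, "XG": -55.56, "XS": -43.16, "XP": -2063.09, "XA": 1103.46, "XM": -34.36,
      "XFXG": 4.43, "XFXS": -1.41, "XFXP": 2027.37, "XFXA": -1249.55, "XFXM": -23.35,
      "XGXS": -11.19, "XGXP": 1899.63, "XGXA": -1130.07, "XGXM": -22.25,
      "XSXP": 1921.26, "XSXA": -1169.78, "XSXM": -4.93,
      "XPXA": 1987.27, "XPXM": 2819.84, "XAXM": -2024.59
    },
    "anova": {"p_value": "<0.0001", "r_squared": 0.999, "sd": 0.61, "cv_percent": 1.2}
  },
  "tm_prime": {
    "terms": {
      "XF": -42.92, "XG": -42.31, "XS": -33.39, "XP": -72.78, "XA": 13.8, "XM": -10.8,
      "XFXM": -17.99, "XGXM": -21.09, "XSXA": -15.8, "XPXM": 134.61, "XAXM": -172.4
    },
    "anova": {"p_value": "<0.0001", "r_squared": 0.994, "sd": 0.69, "cv_percent": 2.02}
  },
  "ws_prime": {
    "terms": {
      "XF": 0.75, "XG": 0.78, "XS": 0.80, "XP": 51.35, "XA": -36.73, "XM": 0.72,
      "XFXG": 0.08, "XFXS": 0.03, "XFXP": -53.72, "XFXA": 39.01, "XFXM": 0.05,
      "XGXS": 0.02, "XGXP": -52.92, "XGXA": 38.22, "XGXM": -0.30,
      "XSXP": -53.85, "XSXA": 39.16, "XSXM": -0.40,
      "XPXA": -19.73, "XPXM": -65.01, "XAXM": 57.76
    },
    "anova": {"p_value": 0.2143, "r_squared": 0.921, "sd": 0.02, "cv_percent": 2.94}
  }
}
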