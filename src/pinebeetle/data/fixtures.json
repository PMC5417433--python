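{
  "table1_n_per_species": 4,
  "table1": {
    "2013": {
      "ponderosa":     {"dbh_mean": 25.76, "dbh_se": 0.58, "phloem_mean": 2.02, "phloem_se": 0.08},
      "lodgepole":     {"dbh_mean": 24.28, "dbh_se": 0.57, "phloem_mean": 2.01, "phloem_se": 0.07},
      "jack":          {"dbh_mean": 22.63, "dbh_se": 0.71, "phloem_mean": 1.56, "phloem_se": 0.04},
      "red":           {"dbh_mean": 24.63, "dbh_se": 1.30, "phloem_mean": 1.89, "phloem_se": 0.04},
      "eastern_white": {"dbh_mean": 24.60, "dbh_se": 0.78, "phloem_mean": 1.86, "phloem_se": 0.06},
      "scots":         {"dbh_mean": 24.03, "dbh_se": 0.90, "phloem_mean": 1.61, "phloem_se": 0.03}
    },
    "2014": {
      "ponderosa":     {"dbh_mean": 24.22, "dbh_se": 0.21, "phloem_mean": 3.10, "phloem_se": 0.06},
      "lodgepole":     {"dbh_mean": 23.61, "dbh_se": 0.48, "phloem_mean": 3.18, "phloem_se": 0.05},
      "jack":          {"dbh_mean": 22.93, "dbh_se": 0.55, "phloem_mean": 2.00, "phloem_se": 0.06},
      "red":           {"dbh_mean": 23.10, "dbh_se": 0.36, "phloem_mean": 2.47, "phloem_se": 0.04},
      "eastern_white": {"dbh_mean": 24.13, "dbh_se": 0.63, "phloem_mean": 2.50, "phloem_se": 0.10},
      "scots":         {"dbh_mean": 23.56, "dbh_se": 0.93, "phloem_mean": 2.09, "phloem_se": 0.07}
    }
  },
  "exp1_pooled": [532, 840],
  "pooled_stages": {
    "bark":   {"k": 532, "n": 840,  "pct": 63.3},
    "phloem": {"k": 951, "n": 1123, "pct": 84.7},
    "brood":  {"k": 590, "n": 840,  "pct": 70.2}
  },
  "host_class": {
    "ponderosa": "historical",
    "lodgepole": "historical",
    "jack": "novel",
    "red": "novel",
    "eastern_white": "novel",
    "scots": "novel"
  },
  "table2": {
    "ponderosa":     {"24h": [44.0, 36.3, 52.0], "48h": [67.3, 59.4, 74.4], "72h": [74.8, 66.5, 81.7]},
    "lodgepole":     {"24h": [28.0, 19.9, 36.9], "48h": [58.7, 50.6, 66.3], "72h": [68.8, 60.0, 76.4]},
    "jack":          {"24h": [31.3, 23.0, 40.7], "48h": [50.7, 42.7, 58.6], "72h": [56.7, 47.7, 65.3]},
    "red":           {"24h": [38.7, 29.5, 48.4], "48h": [60.0, 52.0, 67.5], "72h": [68.1, 59.3, 75.8]},
    "eastern_white": {"24h": [17.3, 11.2, 24.9], "48h": [28.7, 22.0, 36.4], "72h": [47.3, 38.5, 56.3]},
    "scots":         {"24h": [30.0, 19.7, 42.1], "48h": [57.8, 47.4, 67.5], "72h": [65.7, 54.1, 75.7]}
  }
}
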