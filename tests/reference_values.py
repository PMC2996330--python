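"""Published reference values used by the acceptance tests.

Values are stored as printed (strings), so tests can derive the tolerance
"±1 in the last printed digit" from the formatting itself.
"""

# (K, Vm) combinations, column order of the analytic-index reference grid
GRID = [
    (0.005, 0.05), (0.005, 0.1), (0.005, 0.2),
    (0.01, 0.05), (0.01, 0.1), (0.01, 0.2),
    (0.05, 0.05), (0.05, 0.1), (0.05, 0.2),
    (0.1, 0.05), (0.1, 0.1), (0.1, 0.2),
]

# index -> 12 printed values in GRID order
GRID_TABLE = {
    "auc_exact": ["0.678", "0.746", "0.832", "0.666", "0.730", "0.814",
                  "0.635", "0.690", "0.765", "0.622", "0.672", "0.742"],
    "auc_binormal_equal": ["0.677", "0.742", "0.821", "0.665", "0.726",
                           "0.803", "0.634", "0.686", "0.754", "0.621",
                           "0.669", "0.731"],
    "auc_binormal_unequal": ["0.679", "0.747", "0.833", "0.667", "0.731",
                             "0.815", "0.636", "0.691", "0.766", "0.623",
                             "0.673", "0.744"],
    "pce_0.1": ["0.258", "0.350", "0.505", "0.241", "0.323", "0.460",
                "0.201", "0.255", "0.346", "0.182", "0.224", "0.293"],
    "pce_0.2": ["0.421", "0.530", "0.691", "0.401", "0.500", "0.650",
                "0.349", "0.421", "0.535", "0.323", "0.382", "0.474"],
    "pce_0.5": ["0.746", "0.831", "0.924", "0.729", "0.812", "0.906",
                "0.681", "0.752", "0.845", "0.656", "0.719", "0.805"],
    "var_risk": ["1.23E-05", "2.90E-05", "7.97E-05", "4.06E-05", "9.27E-05",
                 "2.39E-04", "5.68E-04", "1.21E-03", "2.75E-03", "1.60E-03",
                 "3.34E-03", "7.20E-03"],
    "var_ratio": ["0.0025", "0.0058", "0.0160", "0.0041", "0.0094", "0.0241",
                  "0.0120", "0.0255", "0.0578", "0.0178", "0.0371", "0.0800"],
    "mean_risk_cases": ["0.0075", "0.0108", "0.0209", "0.0141", "0.0193",
                        "0.0339", "0.0614", "0.0743", "0.1049", "0.1160",
                        "0.1334", "0.1720"],
    "mean_risk_noncases": ["0.0050", "0.0050", "0.0049", "0.0100", "0.0099",
                           "0.0098", "0.0494", "0.0487", "0.0472", "0.0982",
                           "0.0963", "0.0921"],
    "slope": ["0.0025", "0.0058", "0.0160", "0.0041", "0.0094", "0.0241",
              "0.0120", "0.0255", "0.0577", "0.0178", "0.0371", "0.0799"],
    "risk_p10": ["0.0017", "0.0008", "0.0002", "0.0037", "0.0020", "0.0006",
                 "0.0238", "0.0153", "0.0066", "0.0538", "0.0377", "0.0191"],
    "risk_p90": ["0.0094", "0.0111", "0.0126", "0.0182", "0.0214", "0.0250",
                 "0.0817", "0.0957", "0.1154", "0.1537", "0.1778", "0.2142"],
    "rr_10_90": ["5.68", "13.21", "58.42", "4.95", "10.76", "42.06", "3.44",
                 "6.23", "17.56", "2.85", "4.72", "11.24"],
    "range_10_90": ["0.0078", "0.0102", "0.0124", "0.0145", "0.0194",
                    "0.0244", "0.0580", "0.0803", "0.1088", "0.0998",
                    "0.1401", "0.1951"],
}

# rows: (K, v_old, v_new, NRI, AUC increase, IDI); thresholds 6% and 20%
IMPROVEMENT_TABLE = [
    (0.05, 0.05, 0.10, 0.099, 0.055, 0.014),
    (0.05, 0.05, 0.15, 0.195, 0.096, 0.029),
    (0.05, 0.10, 0.15, 0.102, 0.041, 0.015),
    (0.05, 0.10, 0.20, 0.202, 0.075, 0.032),
    (0.05, 0.20, 0.25, 0.104, 0.029, 0.019),
    (0.05, 0.20, 0.30, 0.201, 0.054, 0.040),
    (0.10, 0.05, 0.10, 0.166, 0.050, 0.019),
    (0.10, 0.05, 0.15, 0.306, 0.089, 0.040),
    (0.10, 0.10, 0.15, 0.142, 0.038, 0.021),
    (0.10, 0.10, 0.20, 0.262, 0.070, 0.043),
    (0.10, 0.20, 0.25, 0.109, 0.028, 0.024),
    (0.10, 0.20, 0.30, 0.205, 0.053, 0.049),
]

# disease -> (printed K, printed Vm, {index: printed value})
DISEASE_TABLE = {
    "bipolar": ("0.021", "0.0214", {
        "auc_exact": "0.600", "auc_binormal_equal": "0.600",
        "auc_binormal_unequal": "0.601",
        "pce_0.1": "0.174", "pce_0.2": "0.310", "pce_0.5": "0.639",
        "var_risk": "5.68E-05", "var_ratio": "0.0028",
        "mean_risk_cases": "0.0237", "mean_risk_noncases": "0.0209",
        "slope": "0.0028", "risk_p10": "0.0124", "risk_p90": "0.0310",
        "rr_10_90": "2.50", "range_10_90": "0.019"}),
    "breast_cancer": ("0.127", "0.057", {
        "auc_exact": "0.625", "auc_binormal_equal": "0.624",
        "auc_binormal_unequal": "0.626",
        "pce_0.1": "0.181", "pce_0.2": "0.322", "pce_0.5": "0.656",
        "var_risk": "2.56E-03", "var_ratio": "0.0231",
        "mean_risk_cases": "0.1472", "mean_risk_noncases": "0.1241",
        "slope": "0.0231", "risk_p10": "0.0682", "risk_p90": "0.1950",
        "rr_10_90": "2.86", "range_10_90": "0.127"}),
    "coronary_artery_disease": ("0.3365", "0.123", {
        "auc_exact": "0.662", "auc_binormal_equal": "0.658",
        "auc_binormal_unequal": "0.664",
        "pce_0.1": "0.173", "pce_0.2": "0.314", "pce_0.5": "0.655",
        "var_risk": "1.66E-02", "var_ratio": "0.0745",
        "mean_risk_cases": "0.3859", "mean_risk_noncases": "0.3114",
        "slope": "0.0745", "risk_p10": "0.1759", "risk_p90": "0.5119",
        "rr_10_90": "2.91", "range_10_90": "0.336"}),
    "crohn_disease": ("0.0060", "0.074", {
        "auc_exact": "0.711", "auc_binormal_equal": "0.708",
        "auc_binormal_unequal": "0.712",
        "pce_0.1": "0.298", "pce_0.2": "0.471", "pce_0.5": "0.788",
        "var_risk": "2.66E-05", "var_ratio": "0.0045",
        "mean_risk_cases": "0.0104", "mean_risk_noncases": "0.0059",
        "slope": "0.0045", "risk_p10": "0.0015", "risk_p90": "0.0122",
        "rr_10_90": "8.32", "range_10_90": "0.011"}),
    "prostate_cancer": ("0.156", "0.125", {
        "auc_exact": "0.680", "auc_binormal_equal": "0.675",
        "auc_binormal_unequal": "0.681",
        "pce_0.1": "0.218", "pce_0.2": "0.376", "pce_0.5": "0.716",
        "var_risk": "7.62E-03", "var_ratio": "0.0578",
        "mean_risk_cases": "0.2048", "mean_risk_noncases": "0.1470",
        "slope": "0.0578", "risk_p10": "0.0588", "risk_p90": "0.2754",
        "rr_10_90": "4.69", "range_10_90": "0.217"}),
    "schizophrenia": ("0.0072", "0.003", {
        "auc_exact": "0.543", "auc_binormal_equal": "0.544",
        "auc_binormal_unequal": "0.544",
        "pce_0.1": "0.130", "pce_0.2": "0.246", "pce_0.5": "0.562",
        "var_risk": "1.28E-06", "var_ratio": "0.0002",
        "mean_risk_cases": "0.0074", "mean_risk_noncases": "0.0072",
        "slope": "0.0002", "risk_p10": "0.0058", "risk_p90": "0.0087",
        "rr_10_90": "1.49", "range_10_90": "0.003"}),
    "lupus": ("0.0031", "0.087", {
        "auc_exact": "0.741", "auc_binormal_equal": "0.738",
        "auc_binormal_unequal": "0.742",
        "pce_0.1": "0.345", "pce_0.2": "0.523", "pce_0.5": "0.825",
        "var_risk": "1.05E-05", "var_ratio": "0.0034",
        "mean_risk_cases": "0.0065", "mean_risk_noncases": "0.0031",
        "slope": "0.0034", "risk_p10": "0.0005", "risk_p90": "0.0067",
        "rr_10_90": "12.23", "range_10_90": "0.006"}),
    "type1_diabetes": ("0.0066", "0.109", {
        "auc_exact": "0.750", "auc_binormal_equal": "0.745",
        "auc_binormal_unequal": "0.751",
        "pce_0.1": "0.353", "pce_0.2": "0.535", "pce_0.5": "0.835",
        "var_risk": "5.24E-05", "var_ratio": "0.0079",
        "mean_risk_cases": "0.0145", "mean_risk_noncases": "0.0066",
        "slope": "0.0079", "risk_p10": "0.0011", "risk_p90": "0.0148",
        "rr_10_90": "13.92", "range_10_90": "0.014"}),
    "type2_diabetes": ("0.2895", "0.118", {
        "auc_exact": "0.661", "auc_binormal_equal": "0.657",
        "auc_binormal_unequal": "0.663",
        "pce_0.1": "0.180", "pce_0.2": "0.324", "pce_0.5": "0.664",
        "var_risk": "1.41E-02", "var_ratio": "0.0687",
        "mean_risk_cases": "0.3383", "mean_risk_noncases": "0.2696",
        "slope": "0.0687", "risk_p10": "0.1444", "risk_p90": "0.4517",
        "rr_10_90": "3.13", "range_10_90": "0.307"}),
}
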