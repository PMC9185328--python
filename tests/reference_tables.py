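"""Published reference results used by the metric reproduction suite.

Micro-aggregated confusion counts (TP, TN, FP, FN) reported for eight
ImageNet-pretrained backbones on two Alzheimer's MRI benchmarks (a 4-class
dementia-stage dataset and a 3-class NC/MCI/AD dataset), together with the
rate-metric values printed alongside them.  Percent-style metrics are in
percent; FNR/FDR/Fallout are plain fractions, as printed.

``EXPECTED_DISCREPANT`` lists the (dataset, model, metric) cells whose printed
value is not arithmetically consistent with the printed counts (they came from
streaming/thresholded metric variants); the suite reports these as
discrepancies instead of asserting them.
"""

CONFUSION = {
    "dementia4": {
        "DenseNet201": (9097, 35317, 2963, 3663),
        "MobileNet": (12360, 37953, 423, 432),
        "MobileNetV2": (7055, 37792, 608, 5745),
        "MobileNetV3Small": (5642, 34055, 4333, 7154),
        "MobileNetV3Large": (4307, 36976, 1424, 8493),
        "VGG16": (4317, 36823, 1577, 8483),
        "VGG19": (7258, 33922, 4478, 5542),
        "Xception": (6324, 35897, 2503, 6476),
    },
    "adni3": {
        "DenseNet201": (14057, 29351, 601, 919),
        "MobileNet": (14348, 29407, 593, 652),
        "MobileNetV2": (14187, 29439, 513, 789),
        "MobileNetV3Small": (10680, 27402, 2598, 4320),
        "MobileNetV3Large": (11019, 28027, 1973, 3981),
        "VGG16": (11292, 27944, 2016, 3688),
        "VGG19": (12350, 28425, 1495, 2610),
        "Xception": (14365, 29511, 489, 635),
    },
}

PRINTED = {
    "dementia4": {
        "DenseNet201": {"Precision": 71.62, "Recall (Sensitivity)": 71.29, "Specificity": 92.26,
                        "Youden Index": 63.55, "MCC": 63.11, "FNR": 0.287, "FDR": 0.284, "Fallout": 0.077},
        "MobileNet": {"Precision": 96.69, "Recall (Sensitivity)": 96.62, "Specificity": 98.90,
                      "Youden Index": 95.52, "MCC": 95.54, "FNR": 0.034, "FDR": 0.033, "Fallout": 0.011},
        "MobileNetV2": {"Precision": 63.06, "Recall (Sensitivity)": 55.12, "Specificity": 98.42,
                        "Youden Index": 53.53, "MCC": 54.89, "FNR": 0.449, "FDR": 0.129, "Fallout": 0.016},
        "MobileNetV3Small": {"Precision": 56.68, "Recall (Sensitivity)": 44.09, "Specificity": 88.71,
                             "Youden Index": 32.80, "MCC": 35.85, "FNR": 0.559, "FDR": 0.433, "Fallout": 0.113},
        "MobileNetV3Large": {"Precision": 52.84, "Recall (Sensitivity)": 33.65, "Specificity": 96.29,
                             "Youden Index": 29.94, "MCC": 34.92, "FNR": 0.664, "FDR": 0.169, "Fallout": 0.037},
        "VGG16": {"Precision": 66.83, "Recall (Sensitivity)": 33.73, "Specificity": 95.89,
                  "Youden Index": 29.62, "MCC": 37.58, "FNR": 0.663, "FDR": 0.268, "Fallout": 0.041},
        "VGG19": {"Precision": 60.66, "Recall (Sensitivity)": 56.70, "Specificity": 88.34,
                  "Youden Index": 45.04, "MCC": 45.86, "FNR": 0.433, "FDR": 0.393, "Fallout": 0.117},
        "Xception": {"Precision": 71.19, "Recall (Sensitivity)": 49.41, "Specificity": 93.48,
                     "Youden Index": 42.89, "MCC": 48.89, "FNR": 0.506, "FDR": 0.288, "Fallout": 0.065},
    },
    "adni3": {
        "DenseNet201": {"Precision": 95.86, "Recall (Sensitivity)": 93.86, "Specificity": 97.99,
                        "Youden Index": 91.86, "MCC": 92.36, "FNR": 0.061, "FDR": 0.041, "Fallout": 0.020},
        "MobileNet": {"Precision": 96.03, "Recall (Sensitivity)": 95.65, "Specificity": 98.02,
                      "Youden Index": 93.68, "MCC": 93.77, "FNR": 0.043, "FDR": 0.040, "Fallout": 0.020},
        "MobileNetV2": {"Precision": 96.51, "Recall (Sensitivity)": 94.73, "Specificity": 98.29,
                        "Youden Index": 93.02, "MCC": 93.47, "FNR": 0.053, "FDR": 0.035, "Fallout": 0.017},
        "MobileNetV3Small": {"Precision": 80.22, "Recall (Sensitivity)": 71.20, "Specificity": 91.34,
                             "Youden Index": 62.54, "MCC": 64.59, "FNR": 0.288, "FDR": 0.198, "Fallout": 0.087},
        "MobileNetV3Large": {"Precision": 84.82, "Recall (Sensitivity)": 73.46, "Specificity": 93.42,
                             "Youden Index": 66.88, "MCC": 69.60, "FNR": 0.265, "FDR": 0.152, "Fallout": 0.066},
        "VGG16": {"Precision": 84.84, "Recall (Sensitivity)": 75.38, "Specificity": 93.27,
                  "Youden Index": 68.65, "MCC": 70.91, "FNR": 0.246, "FDR": 0.152, "Fallout": 0.067},
        "VGG19": {"Precision": 89.18, "Recall (Sensitivity)": 82.55, "Specificity": 95.00,
                  "Youden Index": 77.56, "MCC": 79.17, "FNR": 0.174, "FDR": 0.108, "Fallout": 0.050},
        "Xception": {"Precision": 96.72, "Recall (Sensitivity)": 95.77, "Specificity": 98.37,
                     "Youden Index": 94.14, "MCC": 97.91, "FNR": 0.042, "FDR": 0.033, "Fallout": 0.016},
    },
}

EXPECTED_DISCREPANT = {
    ("dementia4", "DenseNet201", "Precision"),
    ("dementia4", "DenseNet201", "MCC"),
    ("dementia4", "DenseNet201", "FDR"),
    ("dementia4", "MobileNetV2", "Precision"),
    ("dementia4", "MobileNetV2", "MCC"),
    ("dementia4", "MobileNetV2", "FDR"),
    ("dementia4", "MobileNetV3Small", "Precision"),
    ("dementia4", "MobileNetV3Small", "MCC"),
    ("dementia4", "MobileNetV3Small", "FDR"),
    ("dementia4", "MobileNetV3Large", "Precision"),
    ("dementia4", "MobileNetV3Large", "MCC"),
    ("dementia4", "MobileNetV3Large", "FDR"),
    ("dementia4", "VGG16", "Precision"),
    ("dementia4", "VGG16", "MCC"),
    ("dementia4", "VGG19", "Precision"),
    ("dementia4", "VGG19", "MCC"),
    ("dementia4", "VGG19", "FDR"),
    ("dementia4", "Xception", "Precision"),
    ("dementia4", "Xception", "MCC"),
    ("dementia4", "Xception", "FDR"),
    ("adni3", "DenseNet201", "Precision"),
    ("adni3", "MobileNetV2", "MCC"),
    ("adni3", "MobileNetV3Small", "Precision"),
    ("adni3", "MobileNetV3Small", "MCC"),
    ("adni3", "MobileNetV3Small", "FDR"),
    ("adni3", "MobileNetV3Large", "Precision"),
    ("adni3", "VGG16", "Precision"),
    ("adni3", "VGG16", "MCC"),
    ("adni3", "VGG16", "FDR"),
    ("adni3", "VGG19", "Precision"),
    ("adni3", "VGG19", "MCC"),
    ("adni3", "Xception", "Precision"),
    ("adni3", "Xception", "MCC"),
}
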