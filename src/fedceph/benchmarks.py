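"""Published two-client cephalometric benchmark numbers used as inputs.

Reported mean accuracies of the six DenseNet121-based model variants on the
Dicle + ISBI two-client benchmark, in the centralized (CL), local (LL) and
federated (FL) settings, plus the two datasets' class-count tables.  These
values are inputs to the contribution analysis (the FL-vs-LL gains and
CL-vs-FL sacrifices are plain differences of them); this package does not
attempt to re-derive them, which would require the original radiographs and
GPU-scale training.
"""

from __future__ import annotations

MODEL_VARIANTS = (
    "densenet121",
    "densenet121_ca",
    "densenet121_se",
    "densenet121_sa",
    "densenet121_sa_se",
    "densenet121_spp",
)

#: Mean accuracy in the centralized setting (merged Dicle + ISBI test set).
CL_ACCURACY = {
    "densenet121": 0.5000,
    "densenet121_ca": 0.7333,
    "densenet121_se": 0.7368,
    "densenet121_sa": 0.7272,
    "densenet121_sa_se": 0.7345,
    "densenet121_spp": 0.7244,
}

#: Mean accuracy in the local setting, per client dataset (each model trained
#: on one client's data, tested on the merged test set).
LL_ACCURACY = {
    "dicle": {
        "densenet121": 0.4347,
        "densenet121_ca": 0.6997,
        "densenet121_se": 0.6977,
        "densenet121_sa": 0.7076,
        "densenet121_sa_se": 0.7084,
        "densenet121_spp": 0.6782,
    },
    "isbi": {
        "densenet121": 0.3116,
        "densenet121_ca": 0.5802,
        "densenet121_se": 0.5990,
        "densenet121_sa": 0.5660,
        "densenet121_sa_se": 0.5935,
        "densenet121_spp": 0.4901,
    },
}

#: Mean accuracy in the federated setting (global model, merged test set).
FL_ACCURACY = {
    "densenet121": 0.4367,
    "densenet121_ca": 0.7310,
    "densenet121_se": 0.7340,
    "densenet121_sa": 0.7318,
    "densenet121_sa_se": 0.7457,
    "densenet121_spp": 0.6987,
}

#: Class-count tables of the two client datasets (classes I, II, III).
CLASS_COUNTS = {
    "dicle": {"train": (318, 226, 141), "test": (80, 55, 36), "total": (399, 284, 180)},
    "isbi": {"train": (48, 63, 189), "test": (32, 26, 42), "total": (80, 89, 231)},
}

#: Printed class-ratio rows of the two datasets (rounded to 2 decimals).
CLASS_RATIOS = {"dicle": (0.46, 0.33, 0.21), "isbi": (0.2, 0.22, 0.58)}

BASELINE = "densenet121"
AUGMENTED = tuple(m for m in MODEL_VARIANTS if m != BASELINE)


def min_augmentation_gain(setting_accuracy: dict[str, float]) -> float:
    """Smallest accuracy gain of any augmented variant over the baseline."""
    base = setting_accuracy[BASELINE]
    return min(setting_accuracy[m] - base for m in AUGMENTED)
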