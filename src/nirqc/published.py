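"""Published external-validation tables for the 101-batch Lanqin oral solution study.

The published through-vial NIR study of this formulation deposits no raw
spectra, but it does print the complete external-validation tables: for 11
independent batches, the reference value and the NIR-predicted value of each
indicator under both acquisition systems, together with the summary rows
(Rv, RMSEV, RSEV, Wilcoxon p).  Those printed pairs are exact inputs — the
per-sample columns fully determine every summary metric — so they serve as
a deterministic fixture for the evaluation module: recomputing the metrics
from the pairs must reproduce the printed summary rows.

ANTI-NO is a fraction; the analytes are mg/mL.  ``SYSTEMS`` maps the study's
"traditional" (4 mm tube) and "non-invasive" (through-vial) models.
"""

from __future__ import annotations

from types import MappingProxyType

import numpy as np

__all__ = [
    "SYSTEMS",
    "VALIDATION_PAIRS",
    "PUBLISHED_VALIDATION_SUMMARY",
    "PUBLISHED_DATASET_SUMMARY",
    "PUBLISHED_OPTIMAL_MODELS",
]

SYSTEMS = ("traditional", "non_invasive")

_REFERENCE = {
    "anti_no": (0.4426, 0.8427, 0.6185, 0.5161, 0.6956, 0.4594,
                0.7785, 0.8735, 0.7952, 0.8897, 0.7633),
    "epigoitrin": (0.0425, 0.0702, 0.0381, 0.0305, 0.0452, 0.0185,
                   0.0468, 0.0616, 0.0466, 0.0648, 0.0530),
    "geniposide": (2.396, 5.630, 4.221, 2.631, 4.054, 1.421,
                   5.027, 6.525, 6.437, 5.248, 7.032),
    "baicalin": (0.7825, 2.421, 1.303, 1.295, 1.706, 0.5729,
                 1.608, 2.820, 2.413, 2.014, 2.269),
}

#: per-sample (reference, predicted) columns of the two external-validation tables
VALIDATION_PAIRS = MappingProxyType({
    "traditional": MappingProxyType({
        "anti_no": (
            _REFERENCE["anti_no"],
            (0.4917, 0.8541, 0.5988, 0.5743, 0.6698, 0.4362,
             0.8132, 0.8326, 0.9022, 0.7868, 0.7989),
        ),
        "epigoitrin": (
            _REFERENCE["epigoitrin"],
            (0.02952, 0.07235, 0.02531, 0.02882, 0.03126, 0.01739,
             0.05402, 0.06644, 0.04715, 0.04770, 0.05547),
        ),
        "geniposide": (
            _REFERENCE["geniposide"],
            (2.632, 5.692, 2.897, 2.094, 3.738, 1.239,
             5.152, 6.937, 6.279, 4.650, 6.399),
        ),
        "baicalin": (
            _REFERENCE["baicalin"],
            (0.8637, 2.171, 1.421, 1.172, 1.451, 0.6174,
             1.712, 2.366, 2.449, 2.020, 2.652),
        ),
    }),
    "non_invasive": MappingProxyType({
        "anti_no": (
            _REFERENCE["anti_no"],
            (0.4728, 0.9373, 0.6515, 0.5683, 0.6996, 0.4520,
             0.7173, 0.9306, 0.8521, 0.8075, 0.8206),
        ),
        "epigoitrin": (
            _REFERENCE["epigoitrin"],
            (0.02919, 0.07578, 0.03811, 0.03752, 0.04223, 0.01870,
             0.03451, 0.07149, 0.05203, 0.04884, 0.05317),
        ),
        "geniposide": (
            _REFERENCE["geniposide"],
            (2.056, 6.118, 3.496, 2.755, 3.847, 1.466,
             5.126, 6.323, 5.420, 4.977, 5.813),
        ),
        "baicalin": (
            _REFERENCE["baicalin"],
            (0.9790, 2.518, 1.700, 1.557, 1.796, 0.6290,
             1.585, 2.623, 2.427, 2.099, 2.286),
        ),
    }),
})

#: printed summary rows of the validation tables: Rv, RMSEV, RSEV (%), Wilcoxon p
PUBLISHED_VALIDATION_SUMMARY = MappingProxyType({
    "traditional": MappingProxyType({
        "anti_no": {"Rv": 0.9356, "RMSEV": 0.055, "RSEV": 7.7, "p": 0.8955},
        "epigoitrin": {"Rv": 0.7766, "RMSEV": 0.009, "RSEV": 18.5, "p": 0.7928},
        "geniposide": {"Rv": 0.9516, "RMSEV": 0.540, "RSEV": 11.0, "p": 0.7427},
        "baicalin": {"Rv": 0.9468, "RMSEV": 0.220, "RSEV": 11.7, "p": 1.0},
    }),
    "non_invasive": MappingProxyType({
        "anti_no": {"Rv": 0.9349, "RMSEV": 0.056, "RSEV": 7.8, "p": 0.6936},
        "epigoitrin": {"Rv": 0.8069, "RMSEV": 0.008, "RSEV": 17.3, "p": 0.7928},
        "geniposide": {"Rv": 0.9457, "RMSEV": 0.571, "RSEV": 11.6, "p": 0.6458},
        "baicalin": {"Rv": 0.9670, "RMSEV": 0.174, "RSEV": 9.3, "p": 0.6936},
    }),
})

#: printed dataset summary for the external-validation set (the one dataset
#: whose per-sample values are printed in full, so its summary is recomputable);
#: ANTI-NO mean in percent as printed, std as a fraction
PUBLISHED_DATASET_SUMMARY = MappingProxyType({
    "validation": MappingProxyType({
        "anti_no": {"n": 11, "min": 44.26, "max": 88.97, "mean": 69.77, "std": 0.1644},
        "epigoitrin": {"n": 11, "min": 0.0185, "max": 0.0702, "mean": 0.0471, "std": 0.0151},
        "geniposide": {"n": 11, "min": 1.421, "max": 7.032, "mean": 4.602, "std": 1.842},
        "baicalin": {"n": 11, "min": 0.5729, "max": 2.820, "mean": 1.746, "std": 0.7158},
    }),
})

#: the published optimal-model table (descriptive context only: its inputs —
#: the 101 calibration spectra — were never deposited, so these cells are not
#: recomputable and are kept for report-shape reference, not as expectations
PUBLISHED_OPTIMAL_MODELS = MappingProxyType({
    ("anti_no", "traditional"): {"P.M.": "normalization", "V.S.M.": "random_frog", "V.N.": 290, "LVs": 9, "RPD": 3.20},
    ("anti_no", "non_invasive"): {"P.M.": "msc", "V.S.M.": "sipls", "V.N.": 345, "LVs": 11, "RPD": 3.49},
    ("epigoitrin", "traditional"): {"P.M.": "sg", "V.S.M.": "random_frog", "V.N.": 250, "LVs": 8, "RPD": 3.09},
    ("epigoitrin", "non_invasive"): {"P.M.": "normalization", "V.S.M.": "sipls", "V.N.": 388, "LVs": 11, "RPD": 3.10},
    ("geniposide", "traditional"): {"P.M.": "msc", "V.S.M.": "sipls", "V.N.": 345, "LVs": 13, "RPD": 4.95},
    ("geniposide", "non_invasive"): {"P.M.": "raw", "V.S.M.": "sipls", "V.N.": 208, "LVs": 8, "RPD": 5.29},
    ("baicalin", "traditional"): {"P.M.": "normalization", "V.S.M.": "cars", "V.N.": 47, "LVs": 10, "RPD": 3.92},
    ("baicalin", "non_invasive"): {"P.M.": "msc", "V.S.M.": "cars", "V.N.": 36, "LVs": 7, "RPD": 4.33},
})


def validation_arrays(system: str, indicator: str) -> tuple[np.ndarray, np.ndarray]:
    """(reference, predicted) vectors for one indicator/system cell."""
    ref, pred = VALIDATION_PAIRS[system][indicator]
    return np.asarray(ref, dtype=float), np.asarray(pred, dtype=float)
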