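"""Published per-subject benchmark scores for the 14-subject study.

These are the per-subject accuracy / sensitivity / specificity / F1
scores reported for the go/no-go visual-categorization EEG benchmark
(14 subjects, 25 files each), for the baseline whale-optimized SVM
("existing") and the modified variant with MBPSO-derived coefficients
("proposed"). They ship with the package as the worked example for the
averaging utilities: the published cross-subject averages are the
unweighted means of these rows.

Two cells in the source table are corrupted by misplaced decimal
points ("09195" and "09449."); they are restored here as 0.9195 and
0.9449, the only readings consistent with the published averages.
"""

from __future__ import annotations

import pandas as pd

from eegstress.metrics import MetricSet, average_metrics

SUBJECTS = (
    "cba", "clm", "ega", "fsa", "gro", "hth", "lmi",
    "mba", "mma", "mta", "pla", "sce", "sph", "wpa",
)

# subject -> (accuracy, sensitivity, specificity, f1)
EXISTING: dict[str, tuple[float, float, float, float]] = {
    "cba": (0.9226, 0.9664, 0.6405, 0.9558),
    "clm": (0.9162, 0.9611, 0.6272, 0.9521),
    "ega": (0.9195, 0.9646, 0.6116, 0.9543),
    "fsa": (0.9050, 0.9610, 0.5920, 0.9449),
    "gro": (0.9180, 0.9618, 0.6262, 0.9532),
    "hth": (0.9184, 0.9608, 0.6363, 0.9534),
    "lmi": (0.9213, 0.9636, 0.6345, 0.9552),
    "mba": (0.9127, 0.9626, 0.5969, 0.9501),
    "mma": (0.9142, 0.9586, 0.6262, 0.9509),
    "mta": (0.9141, 0.9608, 0.5986, 0.9512),
    "pla": (0.9184, 0.9596, 0.6363, 0.9536),
    "sce": (0.9173, 0.9611, 0.6307, 0.9527),
    "sph": (0.9262, 0.9681, 0.6271, 0.9583),
    "wpa": (0.9072, 0.9622, 0.5862, 0.9465),
}

PROPOSED: dict[str, tuple[float, float, float, float]] = {
    "cba": (0.9141, 0.9716, 0.9074, 0.9815),
    "clm": (0.9586, 0.9632, 0.9124, 0.9769),
    "ega": (0.9645, 0.9692, 0.9095, 0.9804),
    "fsa": (0.9660, 0.9714, 0.9078, 0.9813),
    "gro": (0.9592, 0.9645, 0.9055, 0.9773),
    "hth": (0.9671, 0.9722, 0.9111, 0.9812),
    "lmi": (0.9623, 0.9675, 0.9122, 0.9790),
    "mba": (0.9660, 0.9707, 0.9112, 0.9813),
    "mma": (0.9627, 0.9699, 0.9052, 0.9794),
    "mta": (0.9674, 0.9729, 0.9038, 0.9821),
    "pla": (0.9649, 0.9705, 0.9055, 0.9806),
    "sce": (0.9614, 0.9664, 0.9060, 0.9787),
    "sph": (0.9642, 0.9650, 0.9154, 0.9806),
    "wpa": (0.9646, 0.9700, 0.9101, 0.9803),
}

#: Cross-subject averages as published (4 decimals).
PUBLISHED_AVERAGES = {
    "existing": MetricSet(0.9165, 0.9623, 0.6193, 0.9523),
    "proposed": MetricSet(0.9602, 0.9689, 0.9087, 0.9800),
}


def metric_sets(method: str) -> list[MetricSet]:
    """Per-subject MetricSet rows for 'existing' or 'proposed'."""
    table = {"existing": EXISTING, "proposed": PROPOSED}[method]
    return [MetricSet(*table[s]) for s in SUBJECTS]


def benchmark_averages(method: str) -> MetricSet:
    """Unweighted mean of the 14 per-subject rows."""
    return average_metrics(metric_sets(method))


def benchmark_table() -> pd.DataFrame:
    """Both methods as one tidy table (one row per subject x method)."""
    rows = []
    for method, table in (("existing", EXISTING), ("proposed", PROPOSED)):
        for s in SUBJECTS:
            acc, sen, spe, f1 = table[s]
            rows.append(
                {
                    "subject": s,
                    "method": method,
                    "accuracy": acc,
                    "sensitivity": sen,
                    "specificity": spe,
                    "f1": f1,
                }
            )
    return pd.DataFrame(rows)
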