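"""Region-level concordance between Z-map hypometabolism and SEEG seizure
onset zones.

The evaluation unit is the region instance: one distinct (patient,
hemisphere, region) combination carrying at least one verified contact. An
instance is SOZ-positive if any of its contacts is flagged as seizure onset,
and hypometabolic if the patient's Z-map selected the region. Cross-
classifying the two binary labels yields a confusion table per stratum
(total, per lobe, per hemisphere) and six metrics: sensitivity (TPR),
specificity (TNR), PPV, NPV, accuracy, and Cohen's kappa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .destrieux import LOBES
from .surface import Parcellation

__all__ = [
    "RegionInstance",
    "ConfusionCounts",
    "MetricsRow",
    "build_region_instances",
    "cross_classify",
    "compute_metrics",
    "stratify_and_report",
]

STRATUM_FLOOR_DEFAULT = 30
METRIC_NAMES = ("TPR", "TNR", "PPV", "NPV", "ACC", "Kappa")


@dataclass(frozen=True)
class RegionInstance:
    """One (patient, hemisphere, region) unit entering the classification."""

    patient_id: str
    hemisphere: str
    region: str
    lobe: str
    is_soz: bool
    is_hypometabolic: bool = False


@dataclass
class ConfusionCounts:
    """2x2 confusion counts (SOZ truth vs hypometabolic prediction)."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass
class MetricsRow:
    """Six performance metrics for one stratum; undefined metrics are NaN and
    named in ``undefined`` rather than silently zeroed."""

    stratum: str
    counts: ConfusionCounts
    tpr: float = math.nan
    tnr: float = math.nan
    ppv: float = math.nan
    npv: float = math.nan
    acc: float = math.nan
    kappa: float = math.nan
    undefined: list = field(default_factory=list)
    insufficient: bool = False


def build_region_instances(
    assignment_report: pd.DataFrame,
    soz_flags: dict[str, bool],
    parcellation: Parcellation,
    patient_id: str = "patient",
) -> list[RegionInstance]:
    """Collapse verified contacts to one instance per (patient, hemisphere,
    region); an instance is SOZ if ANY of its contacts is flagged as onset.

    ``assignment_report`` is the per-contact table from
    ``filter_gray_matter_contacts``; ``soz_flags`` maps contact_id -> onset.
    """
    verified = assignment_report[assignment_report["verified"]]
    missing = set(verified["contact_id"]) - set(soz_flags)
    if missing:
        raise KeyError(f"contacts without an SOZ flag: {sorted(missing)[:5]}")
    instances: dict[tuple[str, str, str], bool] = {}
    lobes: dict[tuple[str, str, str], str] = {}
    for _, row in verified.iterrows():
        rid = int(row["region_id"])
        hemi, name = parcellation.key_of(rid)
        key = (patient_id, hemi, name)
        flag = bool(soz_flags[row["contact_id"]])
        instances[key] = instances.get(key, False) or flag
        lobes[key] = parcellation.lobe_of(rid)
    return [
        RegionInstance(
            patient_id=k[0], hemisphere=k[1], region=k[2], lobe=lobes[k], is_soz=v
        )
        for k, v in sorted(instances.items())
    ]


def cross_classify(
    instances: list[RegionInstance],
    hypometabolic_regions: dict[str, set] | set,
) -> tuple[ConfusionCounts, list[RegionInstance]]:
    """Cross-compare SOZ truth with Z-map hypometabolism per instance.

    ``hypometabolic_regions`` is a set of (hemisphere, region) keys, or a dict
    patient_id -> such a set for multi-patient cohorts. Returns the confusion
    counts and the instances with ``is_hypometabolic`` filled in; counts are
    conserved (TP+FP+FN+TN = number of instances).
    """
    if not instances:
        raise ValueError("no region instances to classify")
    counts = ConfusionCounts()
    labeled = []
    for inst in instances:
        if isinstance(hypometabolic_regions, dict):
            hypo_set = hypometabolic_regions.get(inst.patient_id, set())
        else:
            hypo_set = hypometabolic_regions
        hypo = (inst.hemisphere, inst.region) in hypo_set
        labeled.append(
            RegionInstance(
                patient_id=inst.patient_id,
                hemisphere=inst.hemisphere,
                region=inst.region,
                lobe=inst.lobe,
                is_soz=inst.is_soz,
                is_hypometabolic=hypo,
            )
        )
        if inst.is_soz and hypo:
            counts.tp += 1
        elif not inst.is_soz and hypo:
            counts.fp += 1
        elif inst.is_soz and not hypo:
            counts.fn += 1
        else:
            counts.tn += 1
    return counts, labeled


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def compute_metrics(counts: ConfusionCounts, stratum: str = "Total") -> MetricsRow:
    """Six metrics from a 2x2 table.

    TPR = TP/(TP+FN), TNR = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN),
    ACC = (TP+TN)/N, and Cohen's kappa = (p_o - p_e)/(1 - p_e) with p_o = ACC
    and p_e = [(TP+FN)(TP+FP) + (FP+TN)(FN+TN)] / N^2. Zero denominators yield
    NaN values listed in ``undefined``.
    """
    if counts.n == 0:
        raise ValueError("cannot compute metrics on an empty stratum")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    n = counts.n
    row = MetricsRow(stratum=stratum, counts=counts)
    row.tpr = _safe_div(tp, tp + fn)
    row.tnr = _safe_div(tn, tn + fp)
    row.ppv = _safe_div(tp, tp + fp)
    row.npv = _safe_div(tn, tn + fn)
    row.acc = (tp + tn) / n
    p_o = row.acc
    p_e = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / (n * n)
    row.kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else math.nan
    for name, value in zip(METRIC_NAMES, (row.tpr, row.tnr, row.ppv, row.npv, row.acc, row.kappa)):
        if math.isnan(value):
            row.undefined.append(name)
    return row


def stratify_and_report(
    instances: list[RegionInstance],
    hypometabolic_regions: dict[str, set] | set,
    stratum_floor: int = STRATUM_FLOOR_DEFAULT,
) -> tuple[pd.DataFrame, dict]:
    """Metrics per stratum: Total, each lobe, each hemisphere.

    Strata with fewer instances than ``stratum_floor`` are flagged
    ``insufficient`` and carry no metric values (small strata invite unstable
    estimates, so they are excluded from numeric reporting rather than
    printed). Returns a table in the Category/TPR/TNR/PPV/NPV/ACC/Kappa layout
    plus the raw confusion counts per stratum.
    """
    _, labeled = cross_classify(instances, hypometabolic_regions)

    def subset_counts(keep) -> ConfusionCounts:
        c = ConfusionCounts()
        for inst in labeled:
            if not keep(inst):
                continue
            if inst.is_soz and inst.is_hypometabolic:
                c.tp += 1
            elif not inst.is_soz and inst.is_hypometabolic:
                c.fp += 1
            elif inst.is_soz and not inst.is_hypometabolic:
                c.fn += 1
            else:
                c.tn += 1
        return c

    strata: list[tuple[str, ConfusionCounts]] = [("Total", subset_counts(lambda i: True))]
    for lobe in LOBES:
        strata.append((f"{lobe.capitalize()} lobe", subset_counts(lambda i, l=lobe: i.lobe == l)))
    for hemi in ("left", "right"):
        strata.append(
            (f"{hemi.capitalize()} hemisphere", subset_counts(lambda i, h=hemi: i.hemisphere == h))
        )

    rows = []
    raw = {}
    for name, c in strata:
        raw[name] = {"TP": c.tp, "FP": c.fp, "FN": c.fn, "TN": c.tn, "N": c.n}
        if c.n == 0 or c.n < stratum_floor:
            rows.append(
                {
                    "Category": name,
                    "N": c.n,
                    **{m: math.nan for m in METRIC_NAMES},
                    "Flag": "insufficient",
                }
            )
            continue
        m = compute_metrics(c, stratum=name)
        rows.append(
            {
                "Category": name,
                "N": c.n,
                "TPR": m.tpr,
                "TNR": m.tnr,
                "PPV": m.ppv,
                "NPV": m.npv,
                "ACC": m.acc,
                "Kappa": m.kappa,
                "Flag": ";".join(m.undefined) if m.undefined else "",
            }
        )
    return pd.DataFrame(rows), raw
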