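"""Livak relative quantification of qPCR Ct data and fold-change classes.

For each gene and patient, per-replicate dCt values are formed within each
tissue by subtracting a reference Ct (the arithmetic mean of the reference
genes' Ct values in that replicate, equivalent to the geometric mean of
their template quantities):

    dCt(cancer) = Ct(gene, cancer) - Ct(reference, cancer)
    dCt(mucosa) = Ct(gene, mucosa) - Ct(reference, mucosa)
    ddCt        = mean dCt(cancer) - mean dCt(mucosa)
    ratio       = 2^(-ddCt)

assuming 100% amplification efficiency (the Livak assumption; a Pfaffl
per-gene efficiency correction is available but off by default).
Significance is a two-tailed t-test on the replicate dCt values (Welch by
default).  Ratios are classified as up/down at p < alpha and annotated
with an arrow grade for the magnitude of the fold change:
1 arrow < 2-fold, 2 arrows 2-4, 3 arrows 4-8, 4 arrows >= 8.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ALPHA_DEFAULT = 0.05
ARROW_BOUNDS = (2.0, 4.0, 8.0)
TTEST_VARIANTS = ("welch", "student", "paired")


def reference_ct(
    ct: pd.DataFrame,
    patient: str,
    tissue: str,
    reference_genes: Iterable[str],
) -> dict[int, float]:
    """Per-replicate reference Ct for one (patient, tissue).

    Returns a mapping replicate -> arithmetic mean of the reference
    genes' Ct values in that replicate.  Every reference gene must be
    measured in every replicate of the (patient, tissue) pair.
    """
    refs = sorted(set(reference_genes))
    if not refs:
        raise ValueError("at least one reference gene is required")
    sub = ct[
        (ct["patient"] == str(patient))
        & (ct["tissue"] == tissue)
        & (ct["gene"].isin(refs))
    ]
    replicates = sorted(
        ct.loc[(ct["patient"] == str(patient)) & (ct["tissue"] == tissue), "replicate"]
        .unique()
    )
    out: dict[int, float] = {}
    for rep in replicates:
        rep_rows = sub[sub["replicate"] == rep]
        missing = sorted(set(refs) - set(rep_rows["gene"]))
        if missing:
            raise ValueError(
                f"missing reference measurement(s) {missing} for patient "
                f"{patient!r}, tissue {tissue!r}, replicate {rep}"
            )
        out[int(rep)] = float(rep_rows["ct"].mean())
    return out


def delta_ct(ct_target: float, ct_reference: float) -> float:
    """dCt = Ct(target) - Ct(reference) within one tissue."""
    return ct_target - ct_reference


def fold_change(ddct: float, efficiency: float = 1.0) -> float:
    """Relative expression 2^(-ddCt).

    ``efficiency`` is the amplification efficiency E in [0, 1]; the base
    of the exponent is 1 + E (Pfaffl-style correction), so the default
    E = 1 gives the plain Livak 2^(-ddCt).
    """
    if not (0.0 < efficiency <= 1.0):
        raise ValueError("efficiency must be in (0, 1]")
    return float((1.0 + efficiency) ** (-ddct))


def test_significance(
    dct_cancer: Sequence[float],
    dct_mucosa: Sequence[float],
    variant: str = "welch",
) -> float:
    """Two-tailed t-test p-value comparing replicate dCt values.

    ``variant``: "welch" (unequal variance, default), "student" (pooled
    variance) or "paired" (replicate-paired).  Degenerate zero-variance
    input: equal means give p = 1, different means give p = 0.
    """
    a = np.asarray(dct_cancer, dtype=float)
    b = np.asarray(dct_mucosa, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("at least 2 replicates per group are required")
    if variant not in TTEST_VARIANTS:
        raise ValueError(f"variant must be one of {TTEST_VARIANTS}")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    if variant == "paired":
        if len(a) != len(b):
            raise ValueError("paired test requires equal replicate counts")
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.pvalue)


def classify_expression(
    ratio: float, p_value: float, alpha: float = ALPHA_DEFAULT
) -> tuple[str, int]:
    """Map a (ratio, p) pair to a (direction, arrows) grade.

    Non-significant records (p >= alpha) — and the degenerate ratio of
    exactly 1 — are (\"none\", 0).  Otherwise the direction follows the
    sign of the change and the arrow count grades the symmetric fold
    ``max(ratio, 1/ratio)``: <2 -> 1, [2,4) -> 2, [4,8) -> 3, >=8 -> 4.
    """
    if not (ratio > 0):
        raise ValueError(f"expression ratio must be positive, got {ratio}")
    if p_value >= alpha or ratio == 1.0:
        return ("none", 0)
    direction = "up" if ratio > 1.0 else "down"
    fold = max(ratio, 1.0 / ratio)
    arrows = 1 + sum(fold >= b for b in ARROW_BOUNDS)
    return (direction, arrows)


def classify_table(
    df: pd.DataFrame, alpha: float = ALPHA_DEFAULT
) -> pd.DataFrame:
    """Add direction/arrows columns to a (gene, patient, ratio, p_value) table."""
    out = df.copy()
    calls = [
        classify_expression(r, p, alpha)
        for r, p in zip(out["ratio"], out["p_value"])
    ]
    out["direction"] = [c[0] for c in calls]
    out["arrows"] = [c[1] for c in calls]
    return out


def quantify(
    ct: pd.DataFrame,
    reference_genes: Iterable[str],
    alpha: float = ALPHA_DEFAULT,
    ttest: str = "welch",
    efficiency: float = 1.0,
) -> pd.DataFrame:
    """Quantify every non-reference gene for every patient.

    Returns a tidy table with one row per (gene, patient): the 2^(-ddCt)
    expression ratio (cancer relative to matched mucosa), the t-test
    p-value on replicate dCt values, and the direction/arrows class.
    """
    refs = frozenset(reference_genes)
    rows = []
    for patient in sorted(ct["patient"].unique()):
        ref_ct = {
            t: reference_ct(ct, patient, t, refs) for t in ("cancer", "mucosa")
        }
        p_ct = ct[ct["patient"] == patient]
        genes = sorted(set(p_ct["gene"]) - refs)
        for gene in genes:
            dct = {}
            for tissue in ("cancer", "mucosa"):
                sub = p_ct[(p_ct["gene"] == gene) & (p_ct["tissue"] == tissue)]
                if sub.empty:
                    raise ValueError(
                        f"gene {gene!r} has no {tissue} measurements for "
                        f"patient {patient!r}"
                    )
                dct[tissue] = [
                    delta_ct(row.ct, ref_ct[tissue][int(row.replicate)])
                    for row in sub.itertuples()
                ]
            ddct = float(np.mean(dct["cancer"]) - np.mean(dct["mucosa"]))
            ratio = fold_change(ddct, efficiency=efficiency)
            p_value = test_significance(dct["cancer"], dct["mucosa"], variant=ttest)
            direction, arrows = classify_expression(ratio, p_value, alpha)
            rows.append(
                {
                    "gene": gene,
                    "patient": patient,
                    "ddct": ddct,
                    "ratio": ratio,
                    "p_value": p_value,
                    "direction": direction,
                    "arrows": arrows,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PatientSummary:
    """Per-patient tally of significant expression calls."""

    patient: str
    n_tested: int
    n_up: int
    n_down: int
    n_ns: int

    def __post_init__(self) -> None:
        assert self.n_up + self.n_down + self.n_ns == self.n_tested


@dataclass(frozen=True)
class CrossPatientSummary:
    """Direction calls aggregated across the patient cohort."""

    genes_up_all: tuple[str, ...]
    genes_up_any: tuple[str, ...]
    genes_down_any: tuple[str, ...]
    genes_altered_any: tuple[str, ...]
    genes_never_altered: tuple[str, ...]
    genes_divergent: tuple[str, ...]

    @property
    def n_up_all(self) -> int:
        return len(self.genes_up_all)

    @property
    def n_up_any(self) -> int:
        return len(self.genes_up_any)

    @property
    def n_altered_any(self) -> int:
        return len(self.genes_altered_any)


def summarize_patient(records: pd.DataFrame) -> PatientSummary:
    """Tally up/down/non-significant calls for one patient's records."""
    patients = records["patient"].unique()
    if len(patients) != 1:
        raise ValueError(f"expected one patient, got {sorted(map(str, patients))}")
    if records["gene"].duplicated().any():
        dup = records.loc[records["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicate record for gene {dup!r}")
    counts = records["direction"].value_counts()
    return PatientSummary(
        patient=str(patients[0]),
        n_tested=len(records),
        n_up=int(counts.get("up", 0)),
        n_down=int(counts.get("down", 0)),
        n_ns=int(counts.get("none", 0)),
    )


def cross_patient_summary(records: pd.DataFrame) -> CrossPatientSummary:
    """Aggregate direction calls over all patients on a shared gene panel."""
    panels = records.groupby("patient")["gene"].apply(frozenset)
    if len(set(panels)) != 1:
        raise ValueError("patients were tested on unequal gene panels")
    panel = sorted(panels.iloc[0])
    up = records[records["direction"] == "up"].groupby("gene").size()
    down = records[records["direction"] == "down"].groupby("gene").size()
    n_patients = records["patient"].nunique()
    up_all = tuple(g for g in panel if up.get(g, 0) == n_patients)
    up_any = tuple(g for g in panel if up.get(g, 0) >= 1)
    down_any = tuple(g for g in panel if down.get(g, 0) >= 1)
    altered_any = tuple(sorted(set(up_any) | set(down_any)))
    never = tuple(g for g in panel if g not in altered_any)
    divergent = tuple(sorted(set(up_any) & set(down_any)))
    return CrossPatientSummary(
        genes_up_all=up_all,
        genes_up_any=up_any,
        genes_down_any=down_any,
        genes_altered_any=altered_any,
        genes_never_altered=never,
        genes_divergent=divergent,
    )
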