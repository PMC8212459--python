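"""FPKM expression-pattern classification.

Descriptive fold-change calls (no replicate statistics): undetectable
genes, group-preferential expression, monotone leaf-gradient trends
(Spearman rank correlation), light/dark diurnal contrast, and stress
induction/repression with paired treated/control samples. A small
pseudocount keeps ratios finite; all thresholds are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DETECTION_THRESHOLD = 1.0  # FPKM below this in every sample = undetectable
PSEUDOCOUNT = 0.01


@dataclass(frozen=True)
class PatternCall:
    gene: str
    pattern: str  # e.g. "preferential(leaf)", "increasing", "induced(cold)"
    stats: dict = field(default_factory=dict)


def _check_matrix(matrix: pd.DataFrame) -> None:
    if (matrix.values < 0).any():
        raise ValueError("FPKM values must be non-negative")


def detect_low_expression(
    matrix: pd.DataFrame, threshold: float = DETECTION_THRESHOLD
) -> set[str]:
    """Genes whose FPKM is below ``threshold`` in every sample."""
    _check_matrix(matrix)
    mask = (matrix < threshold).all(axis=1)
    return set(matrix.index[mask])


def group_preference(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    group_a: str,
    group_b: str,
    min_fold: float = 2.0,
    min_fpkm: float = DETECTION_THRESHOLD,
) -> dict[str, PatternCall]:
    """Per-gene preferential-expression call between two sample groups."""
    _check_matrix(matrix)
    samples_a = design.index[design["group"] == group_a]
    samples_b = design.index[design["group"] == group_b]
    if len(samples_a) == 0 or len(samples_b) == 0:
        raise ValueError(f"unknown or empty group among {group_a!r}, {group_b!r}")
    mean_a = matrix[list(samples_a)].mean(axis=1)
    mean_b = matrix[list(samples_b)].mean(axis=1)
    calls = {}
    for gene in matrix.index:
        a, b = float(mean_a[gene]), float(mean_b[gene])
        fold_ab = a / (b + PSEUDOCOUNT)
        fold_ba = b / (a + PSEUDOCOUNT)
        if fold_ab >= min_fold and a >= min_fpkm:
            pattern, fold = f"preferential({group_a})", fold_ab
        elif fold_ba >= min_fold and b >= min_fpkm:
            pattern, fold = f"preferential({group_b})", fold_ba
        else:
            pattern, fold = "none", max(fold_ab, fold_ba)
        calls[gene] = PatternCall(gene, pattern,
                                  {"mean_a": a, "mean_b": b, "fold": fold})
    return calls


def gradient_trend(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    rho_cutoff: float = 0.8,
    peak_fold: float = 2.0,
) -> dict[str, PatternCall]:
    """Trend call along ordered positions (e.g. leaf base-to-tip zones).

    |Spearman rho| >= cutoff gives increasing/decreasing; otherwise an
    interior position >= ``peak_fold`` above all others gives
    peaked(position); otherwise none.
    """
    _check_matrix(matrix)
    grad = design.dropna(subset=["position"]).sort_values("position")
    if len(grad) < 3:
        raise ValueError("gradient analysis needs >= 3 ordered positions")
    samples = list(grad.index)
    positions = grad["position"].to_numpy(dtype=float)
    calls = {}
    for gene in matrix.index:
        values = matrix.loc[gene, samples].to_numpy(dtype=float)
        if np.allclose(values, values[0]):
            calls[gene] = PatternCall(gene, "none", {"rho": 0.0})
            continue
        rho = float(stats.spearmanr(positions, values).statistic)
        if rho >= rho_cutoff:
            calls[gene] = PatternCall(gene, "increasing", {"rho": rho})
        elif rho <= -rho_cutoff:
            calls[gene] = PatternCall(gene, "decreasing", {"rho": rho})
        else:
            peak = int(np.argmax(values))
            others = np.delete(values, peak)
            interior = 0 < peak < len(values) - 1
            if interior and (values[peak] >= peak_fold * others).all():
                calls[gene] = PatternCall(
                    gene, f"peaked({int(positions[peak])})",
                    {"rho": rho, "peak_value": float(values[peak])},
                )
            else:
                calls[gene] = PatternCall(gene, "none", {"rho": rho})
    return calls


def diurnal_contrast(
    matrix: pd.DataFrame,
    series: list[tuple[list[str], list[str]]],
    min_fold: float = 2.0,
) -> dict[str, PatternCall]:
    """Light-elevated call: mean(light)/mean(dark) >= ``min_fold`` must hold
    in every cycle series independently."""
    _check_matrix(matrix)
    for light, dark in series:
        if not light or not dark:
            raise ValueError("each diurnal series needs light and dark samples")
    calls = {}
    for gene in matrix.index:
        folds = []
        for light, dark in series:
            ml = float(matrix.loc[gene, light].mean())
            md = float(matrix.loc[gene, dark].mean())
            folds.append(ml / (md + PSEUDOCOUNT))
        elevated = all(f >= min_fold for f in folds)
        calls[gene] = PatternCall(
            gene, "light-elevated" if elevated else "none", {"folds": folds}
        )
    return calls


def stress_response(
    matrix: pd.DataFrame,
    pairs: list[tuple[str, str]],
    min_fold: float = 2.0,
    min_fpkm: float = DETECTION_THRESHOLD,
    policy: str = "all",
    condition: str = "stress",
) -> dict[str, PatternCall]:
    """Induction/repression calls over (treated, control) sample pairs.

    fold = (treated + 0.01) / (control + 0.01); induced when fold >=
    ``min_fold`` with treated >= ``min_fpkm`` (repressed symmetric);
    per-pair calls combined with the ``all`` or ``any`` policy.
    """
    _check_matrix(matrix)
    if policy not in ("all", "any"):
        raise ValueError("policy must be 'all' or 'any'")
    for t, c in pairs:
        if t not in matrix.columns or c not in matrix.columns:
            raise ValueError(f"unpaired or unknown sample in ({t!r}, {c!r})")
    combine = all if policy == "all" else any
    calls = {}
    for gene in matrix.index:
        folds, induced, repressed = [], [], []
        for t, c in pairs:
            treated = float(matrix.loc[gene, t])
            control = float(matrix.loc[gene, c])
            fold = (treated + PSEUDOCOUNT) / (control + PSEUDOCOUNT)
            folds.append(fold)
            induced.append(fold >= min_fold and treated >= min_fpkm)
            repressed.append(fold <= 1.0 / min_fold and control >= min_fpkm)
        if combine(induced):
            pattern = f"induced({condition})"
        elif combine(repressed):
            pattern = f"repressed({condition})"
        else:
            pattern = "none"
        calls[gene] = PatternCall(gene, pattern, {"folds": folds})
    return calls


def qpcr_concordance(fpkm: np.ndarray, qpcr: np.ndarray) -> float:
    """Squared Pearson correlation between paired FPKM and qPCR
    relative-expression vectors."""
    fpkm = np.asarray(fpkm, dtype=float)
    qpcr = np.asarray(qpcr, dtype=float)
    if fpkm.shape != qpcr.shape or fpkm.ndim != 1 or len(fpkm) < 3:
        raise ValueError("need two paired vectors of equal length >= 3")
    if np.std(fpkm) == 0 or np.std(qpcr) == 0:
        raise ValueError("zero variance in one of the vectors")
    r = float(np.corrcoef(fpkm, qpcr)[0, 1])
    return r * r


# ------------------------------------------------------------ recovery

def _diurnal_series(design: pd.DataFrame) -> list[tuple[list[str], list[str]]]:
    out = []
    diurnal = design[design["analysis"] == "diurnal"]
    for s in sorted(diurnal["series"].dropna().unique()):
        sub = diurnal[diurnal["series"] == s]
        out.append(
            (list(sub.index[sub["phase"] == "light"]),
             list(sub.index[sub["phase"] == "dark"]))
        )
    return out


def _stress_pairs(design: pd.DataFrame, condition: str) -> list[tuple[str, str]]:
    sub = design[(design["analysis"] == "stress") & (design["condition"] == condition)]
    pairs = []
    for pid in sorted(sub["pair"].dropna().unique()):
        p = sub[sub["pair"] == pid]
        pairs.append(
            (p.index[p["role"] == "treated"][0], p.index[p["role"] == "control"][0])
        )
    return pairs


def evaluate_fixture_recovery(
    matrix: pd.DataFrame, design: pd.DataFrame, truth: pd.DataFrame
) -> pd.DataFrame:
    """Score planted expression patterns against the calls the classifiers
    make; returns a per-gene table with a boolean ``recovered`` column."""
    low = detect_low_expression(matrix)
    tissue = group_preference(matrix, design, "leaf", "stalk")
    gradient = gradient_trend(matrix, design)
    diurnal = diurnal_contrast(matrix, _diurnal_series(design))
    drought = stress_response(matrix, _stress_pairs(design, "drought"),
                              condition="drought")
    cold = stress_response(matrix, _stress_pairs(design, "cold"),
                           condition="cold")

    rows = []
    for gene, planted in truth["pattern"].items():
        if planted == "undetectable":
            ok = gene in low
        elif planted == "constitutive":
            ok = gene not in low and tissue[gene].pattern == "none"
        elif planted == "leaf-preferential":
            ok = tissue[gene].pattern == "preferential(leaf)"
        elif planted == "gradient-increasing":
            ok = gradient[gene].pattern == "increasing"
        elif planted == "gradient-decreasing":
            ok = gradient[gene].pattern == "decreasing"
        elif planted == "gradient-peaked":
            ok = gradient[gene].pattern.startswith("peaked")
        elif planted == "light-elevated":
            ok = diurnal[gene].pattern == "light-elevated"
        elif planted == "drought-induced":
            ok = drought[gene].pattern == "induced(drought)"
        elif planted == "cold-induced-200x":
            ok = cold[gene].pattern == "induced(cold)" and all(
                f >= 100 for f in cold[gene].stats["folds"]
            )
        else:
            raise ValueError(f"unknown planted pattern {planted!r}")
        rows.append(dict(gene=gene, planted=planted, recovered=bool(ok)))
    return pd.DataFrame(rows).set_index("gene")
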