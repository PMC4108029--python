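"""Replicate-aware isoform expression ingestion and usage analytics.

Quantification arrives as per-isoform FPKM with exactly two biological
replicates per sample.  An isoform counts as detected in a sample only when
both replicates reach 1 FPKM; the working value is then the replicate mean.
On top of the merged matrix the module computes the paper-style isoform
usage statistics: per-sample major isoforms, detected-isoform sharing
between sample groups, abundance-rank and top-2 ratio distributions,
major-isoform recurrence, the two-major-isoform log2 switching matrix, PCA,
and two-group differential tests with Benjamini–Hochberg FDR control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import PipelineThresholds

__all__ = [
    "ExpressionTable",
    "ExpressionMatrix",
    "SwitchingMatrix",
    "merge_replicates",
    "major_isoform",
    "isoform_sharing",
    "summarize_isoform_usage",
    "switching_matrix",
    "pca_scores",
    "group_differential",
]


@dataclass
class ExpressionTable:
    """Long-format FPKM records: isoform, gene, sample, replicate ∈ {1,2}."""

    frame: pd.DataFrame  # columns: isoform, gene, sample, replicate, fpkm
    metadata: pd.DataFrame | None = None  # index: sample; e.g. tissue/genotype

    def __post_init__(self):
        required = {"isoform", "gene", "sample", "replicate", "fpkm"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"expression table missing columns {sorted(missing)}")
        if (self.frame["fpkm"] < 0).any():
            raise ValueError("negative FPKM values")
        counts = self.frame.groupby(["isoform", "sample"])["replicate"].agg(
            ["count", "nunique"]
        )
        bad = counts[(counts["count"] != 2) | (counts["nunique"] != 2)]
        if len(bad):
            iso, sample = bad.index[0]
            raise ValueError(
                f"isoform {iso!r} sample {sample!r}: expected exactly two replicates"
            )

    @classmethod
    def from_tsv(cls, path, metadata_path=None) -> "ExpressionTable":
        frame = pd.read_csv(path, sep="\t", comment="#")
        meta = None
        if metadata_path is not None:
            meta = pd.read_csv(metadata_path, sep="\t", comment="#").set_index("sample")
        return cls(frame, meta)


@dataclass
class ExpressionMatrix:
    """Isoform × sample replicate-mean values with a detection mask."""

    values: pd.DataFrame  # replicate means (NaN where not detected)
    detected: pd.DataFrame  # boolean
    gene_of: pd.Series  # isoform → gene
    metadata: pd.DataFrame | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def isoforms_of(self, gene: str) -> list[str]:
        return list(self.gene_of.index[self.gene_of == gene])

    def gene_values(self) -> pd.DataFrame:
        """Gene-level expression: sum of detected isoform values (0 if none)."""
        filled = self.values.where(self.detected, 0.0).fillna(0.0)
        return filled.groupby(self.gene_of).sum()

    def gene_detected(self) -> pd.DataFrame:
        return self.detected.groupby(self.gene_of).any()


def merge_replicates(
    tab: ExpressionTable, th: PipelineThresholds | None = None
) -> ExpressionMatrix:
    """Merge replicate pairs into detection-masked means.

    Detected iff both replicates ≥ detection threshold; value = replicate
    mean where detected (NaN otherwise).
    """
    th = th or PipelineThresholds()
    wide = tab.frame.pivot_table(
        index=["isoform", "gene"], columns=["sample", "replicate"], values="fpkm"
    )
    if wide.isna().any().any():
        raise ValueError("missing replicate measurements after pivot")
    samples = sorted({s for s, _ in wide.columns})
    rep1 = wide.loc[:, [(s, 1) for s in samples]]
    rep2 = wide.loc[:, [(s, 2) for s in samples]]
    rep1.columns = rep2.columns = samples
    detected = (rep1 >= th.detection_fpkm) & (rep2 >= th.detection_fpkm)
    means = (rep1 + rep2) / 2.0
    values = means.where(detected)
    gene_of = pd.Series(
        {iso: gene for iso, gene in values.index}, name="gene"
    )
    values.index = [iso for iso, _ in values.index]
    detected.index = values.index
    values = values.sort_index()
    detected = detected.sort_index()
    gene_of = gene_of.sort_index()
    return ExpressionMatrix(values, detected, gene_of, tab.metadata)


def major_isoform(m: ExpressionMatrix, gene: str, sample: str) -> str | None:
    """Most abundant detected isoform of a gene in one sample.

    Ties break to the lexicographically smallest isoform id; returns None
    when no isoform is detected.
    """
    isoforms = m.isoforms_of(gene)
    if not isoforms:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    best_id, best_val = None, -math.inf
    for iso in sorted(isoforms):
        if sample not in m.detected.columns:
            raise KeyError(f"sample {sample!r} not in expression matrix")
        if not m.detected.at[iso, sample]:
            continue
        v = m.values.at[iso, sample]
        if v > best_val:
            best_id, best_val = iso, v
    return best_id


def isoform_sharing(m: ExpressionMatrix, grouping: dict[str, str]) -> dict:
    """Detected-isoform sharing between sample groups.

    Only genes detected in every sample are considered (removing the bias
    from genes switched off somewhere); an isoform belongs to a group when
    it is detected in at least one of the group's samples.  Reports
    per-group sets and all intersection-region counts and percentages.
    """
    groups: dict[str, list[str]] = {}
    for sample, grp in grouping.items():
        groups.setdefault(grp, []).append(sample)
    if len(groups) < 2:
        raise ValueError("isoform sharing requires at least two groups")
    for grp, samples in groups.items():
        if not samples:
            raise ValueError(f"group {grp!r} is empty")

    gene_det = m.gene_detected()
    everywhere = set(gene_det.index[gene_det.all(axis=1)])
    keep = m.gene_of.isin(everywhere)
    det = m.detected.loc[keep]

    group_sets = {
        grp: set(det.index[det[samples].any(axis=1)])
        for grp, samples in sorted(groups.items())
    }
    union = set().union(*group_sets.values())
    names = sorted(group_sets)
    regions = {}
    for iso in union:
        member = frozenset(g for g in names if iso in group_sets[g])
        regions[member] = regions.get(member, 0) + 1
    region_counts = {
        "&".join(sorted(k)): v for k, v in sorted(regions.items(), key=lambda kv: sorted(kv[0]))
    }
    shared_all = regions.get(frozenset(names), 0)
    return {
        "genes_considered": len(everywhere),
        "group_sets": group_sets,
        "region_counts": region_counts,
        "region_percent": {
            k: 100.0 * v / len(union) if union else 0.0 for k, v in region_counts.items()
        },
        "shared_all_count": shared_all,
        "shared_all_percent": 100.0 * shared_all / len(union) if union else 0.0,
    }


def summarize_isoform_usage(m: ExpressionMatrix) -> dict:
    """Abundance-rank, top-2 ratio, co-expression and recurrence statistics."""
    rank_values: dict[int, list[float]] = {1: [], 2: [], 3: []}
    ratios: list[float] = []
    coexpressed: list[int] = []
    recurrence_genes = 0
    recurrent = 0

    genes = sorted(set(m.gene_of))
    for gene in genes:
        isoforms = m.isoforms_of(gene)
        majors = []
        for sample in m.samples:
            vals = sorted(
                (
                    float(m.values.at[iso, sample])
                    for iso in isoforms
                    if m.detected.at[iso, sample]
                ),
                reverse=True,
            )
            if not vals:
                continue
            for r in (1, 2, 3):
                if len(vals) >= r:
                    rank_values[r].append(vals[r - 1])
            if len(vals) >= 2 and vals[1] > 0:
                ratios.append(vals[0] / vals[1])
            coexpressed.append(len(vals))
            majors.append(major_isoform(m, gene, sample))
        if len(majors) >= 2:
            recurrence_genes += 1
            if len(set(majors)) == 1:
                recurrent += 1

    n_cases = len(ratios)
    return {
        "rank_fpkm": rank_values,
        "top2_ratios": ratios,
        "frac_ratio_ge2": sum(r >= 2 for r in ratios) / n_cases if n_cases else 0.0,
        "frac_ratio_ge5": sum(r >= 5 for r in ratios) / n_cases if n_cases else 0.0,
        "coexpressed_counts": coexpressed,
        "recurrence_genes": recurrence_genes,
        "recurrent_major": recurrent,
        "recurrence_fraction": recurrent / recurrence_genes if recurrence_genes else 0.0,
    }


@dataclass
class SwitchingMatrix:
    """Gene × sample log2 ratio of each gene's two designated major isoforms."""

    log_ratios: pd.DataFrame
    designation: dict[str, tuple[str, str]]  # gene → (iso1, iso2)
    metadata: pd.DataFrame | None = None


def switching_matrix(
    m: ExpressionMatrix, th: PipelineThresholds | None = None
) -> SwitchingMatrix:
    """Per-gene log2 ratio of the two most broadly detected isoforms.

    The two designated isoforms are those detected in the most samples
    (ties: higher summed FPKM, then id).  Undetected values are floored at
    the detection threshold before the ratio, so a row is defined in every
    sample; genes lacking two isoforms detected somewhere are dropped.
    """
    th = th or PipelineThresholds()
    if len(m.samples) < 2:
        raise ValueError("switching analysis requires at least two samples")
    floor = th.detection_fpkm
    rows, designation = {}, {}
    for gene in sorted(set(m.gene_of)):
        isoforms = m.isoforms_of(gene)
        if len(isoforms) < 2:
            continue
        ranked = sorted(
            isoforms,
            key=lambda iso: (
                -int(m.detected.loc[iso].sum()),
                -float(m.values.loc[iso].fillna(0).sum()),
                iso,
            ),
        )
        iso1, iso2 = ranked[0], ranked[1]
        if m.detected.loc[iso1].sum() == 0 or m.detected.loc[iso2].sum() == 0:
            continue
        v1 = m.values.loc[iso1].fillna(floor).clip(lower=floor)
        v2 = m.values.loc[iso2].fillna(floor).clip(lower=floor)
        rows[gene] = np.log2(v1 / v2)
        designation[gene] = (iso1, iso2)
    frame = pd.DataFrame(rows).T
    if len(frame):
        frame.columns = m.samples
    return SwitchingMatrix(frame, designation, m.metadata)


def pca_scores(X: np.ndarray, n_components: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """PCA by SVD of the column-centered matrix (rows = observations).

    Returns (scores, component variances); no unit-variance scaling.  Signs
    are fixed so each component's largest-magnitude loading is positive.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or min(X.shape) < 2:
        raise ValueError("PCA requires a 2-D matrix with ≥2 rows and columns")
    if np.isnan(X).any():
        raise ValueError("PCA input contains missing values")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, len(s))
    # deterministic sign convention
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    scores = U[:, :k] * s[:k]
    variances = (s[:k] ** 2) / (X.shape[0] - 1)
    return scores, variances


def group_differential(
    values: pd.DataFrame,
    grouping: dict[str, str],
    panel: list[str] | None = None,
    th: PipelineThresholds | None = None,
) -> pd.DataFrame:
    """Two-group Welch t-tests per feature with BH FDR control.

    ``values`` is feature × sample; ``grouping`` maps samples to exactly two
    group labels, each with ≥2 samples.  Features with zero variance in both
    groups get p = 1 and are flagged.  Returns a frame with t, p, q and a
    significance flag at q ≤ fdr_alpha.
    """
    th = th or PipelineThresholds()
    if panel is not None:
        values = values.loc[[f for f in panel if f in values.index]]
    labels = sorted(set(grouping.values()))
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    g1 = [s for s in values.columns if grouping.get(s) == labels[0]]
    g2 = [s for s in values.columns if grouping.get(s) == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least two samples")

    records = []
    for feat in values.index:
        a = values.loc[feat, g1].to_numpy(dtype=float)
        b = values.loc[feat, g2].to_numpy(dtype=float)
        if np.var(a) == 0 and np.var(b) == 0:
            records.append((feat, 0.0, 1.0, True))
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        records.append((feat, float(t), float(p), False))
    out = pd.DataFrame(records, columns=["feature", "t", "p", "zero_variance"])
    out = out.set_index("feature")
    if len(out):
        _, q, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
        out["q"] = q
    else:
        out["q"] = []
    out["significant"] = out["q"] <= th.fdr_alpha
    return out
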