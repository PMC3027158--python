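"""Two-channel MeDIP-chip analysis.

The workflow mirrors a classic GeneSpring-era pipeline: per-probe
Cy5/Cy3 ratios, per-probe normalization to the control-group mean,
presence / raw-intensity / replicate-SD filters, Welch t-tests with a
fold-change cut to call hypo- and hypermethylated probes, gene-level
aggregation, median-based methylation classes, PCA sample scores, and
hypergeometric term enrichment with Benjamini-Hochberg correction.

Sample groups are ``control`` and ``tumor`` (biological), plus the
artificial ``positive`` (fully methylated) and ``negative`` (amplified,
unmethylated) control samples. Positive/negative samples take part in
presence counting and PCA but are excluded from the normalization
reference and from testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .probes import ArrayDesign

__all__ = [
    "AnalysisParams",
    "NormalizedMatrix",
    "BIOLOGICAL_GROUPS",
    "read_channel_table",
    "write_channel_table",
    "compute_ratios",
    "normalize_to_control",
    "filter_probes",
    "welch_test",
    "differential_probes",
    "probe_to_gene",
    "median_classes",
    "pca_scores",
    "term_enrichment",
    "expression_overlap",
    "run_analysis",
]

BIOLOGICAL_GROUPS = ("control", "tumor")
CHANNEL_COLUMNS = ["sample_id", "group", "probe_id", "cy3", "cy5", "present"]


@dataclass(frozen=True)
class AnalysisParams:
    present_min: int = 4
    n_samples_for_present: int = 10
    intensity_min: float = 25.0
    sd_max: float = 1.4
    fc_cut: float = 1.5
    alpha: float = 0.05
    median_fold: float = 2.0
    enrichment_fdr: float = 0.05
    log_scale: bool = False  # Welch test on log2 ratios instead of linear

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fc_cut <= 1 or self.median_fold <= 1:
            raise ValueError("fc_cut and median_fold must be > 1")


@dataclass
class NormalizedMatrix:
    """Probe x sample normalized ratios with group labels and filter audit."""

    ratios: pd.DataFrame  # index: probe_id, columns: sample_id
    groups: pd.Series  # sample_id -> group
    filter_status: pd.Series | None = None  # probe_id -> "kept" or reason

    def biological_samples(self) -> list[str]:
        return [s for s in self.ratios.columns if self.groups[s] in BIOLOGICAL_GROUPS]

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.ratios.columns if self.groups[s] == group]


# ---------------------------------------------------------------------------
# Channel table IO

def read_channel_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CHANNEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"channel table missing columns: {sorted(missing)}")
    df["present"] = df["present"].astype(bool)
    return df


def write_channel_table(channels: pd.DataFrame, path: str | Path) -> None:
    channels.to_csv(path, sep="\t", index=False, columns=CHANNEL_COLUMNS)


def _groups_of(channels: pd.DataFrame) -> pd.Series:
    return channels.drop_duplicates("sample_id").set_index("sample_id")["group"]


# ---------------------------------------------------------------------------
# Ratios and normalization

def compute_ratios(channels: pd.DataFrame) -> pd.DataFrame:
    """Raw per-probe per-sample Cy5/Cy3 ratios; entries with Cy3 <= 0 are NaN."""
    df = channels.copy()
    valid = df["cy3"] > 0
    df["ratio"] = np.where(valid, df["cy5"] / df["cy3"].where(valid), np.nan)
    return df.pivot(index="probe_id", columns="sample_id", values="ratio")


def normalize_to_control(raw_ratios: pd.DataFrame, groups: pd.Series) -> NormalizedMatrix:
    """Divide each probe's ratios by its mean over control biological samples.

    Positive/negative artificial samples are excluded from the reference
    mean; after normalization the control-group mean of every usable
    probe is exactly 1.
    """
    controls = [s for s in raw_ratios.columns if groups.get(s) == "control"]
    if not controls:
        raise ValueError("no control-group samples to normalize against")
    ref = raw_ratios[controls].mean(axis=1)
    usable = ref > 0
    norm = raw_ratios.div(ref.where(usable), axis=0)
    mat = NormalizedMatrix(ratios=norm, groups=groups.copy())
    mat.filter_status = pd.Series(
        np.where(usable, "kept", "unusable:control_mean_nonpositive"), index=raw_ratios.index
    )
    return mat


# ---------------------------------------------------------------------------
# Filters

def filter_probes(
    matrix: NormalizedMatrix,
    channels: pd.DataFrame,
    params: AnalysisParams = AnalysisParams(),
) -> tuple[NormalizedMatrix, dict[str, int]]:
    """Apply presence, raw-intensity and replicate-SD filters.

    A probe is retained iff it is flagged present in at least
    ``present_min`` samples (all samples count, including the artificial
    controls), its mean raw Cy5 over biological samples reaches
    ``intensity_min``, and the SD of its normalized ratios within each
    biological group stays at or below ``sd_max``.
    """
    idx = matrix.ratios.index
    status = (
        matrix.filter_status.reindex(idx).fillna("kept")
        if matrix.filter_status is not None
        else pd.Series("kept", index=idx)
    ).copy()

    valid = channels["cy3"] > 0
    present_counts = (
        channels[valid & channels["present"]].groupby("probe_id").size().reindex(idx).fillna(0)
    )
    bio = channels[channels["group"].isin(BIOLOGICAL_GROUPS)]
    mean_cy5 = bio.groupby("probe_id")["cy5"].mean().reindex(idx)

    ok = status == "kept"
    presence_fail = ok & (present_counts < params.present_min)
    status[presence_fail] = "removed:presence"
    ok &= ~presence_fail

    intensity_fail = ok & (mean_cy5 < params.intensity_min)
    status[intensity_fail] = "removed:intensity"
    ok &= ~intensity_fail

    sd_fail = pd.Series(False, index=idx)
    for group in BIOLOGICAL_GROUPS:
        cols = matrix.samples_in(group)
        if len(cols) >= 2:
            sd_fail |= matrix.ratios[cols].std(axis=1, ddof=1) > params.sd_max
    sd_fail &= ok
    status[sd_fail] = "removed:sd"
    ok &= ~sd_fail

    audit = {
        "input_probes": int(len(idx)),
        "removed_unusable": int((status == "unusable:control_mean_nonpositive").sum()),
        "removed_presence": int(presence_fail.sum()),
        "removed_intensity": int(intensity_fail.sum()),
        "removed_sd": int(sd_fail.sum()),
        "retained": int(ok.sum()),
    }
    filtered = NormalizedMatrix(
        ratios=matrix.ratios.loc[ok], groups=matrix.groups.copy(), filter_status=status
    )
    return filtered, audit


# ---------------------------------------------------------------------------
# Welch test

def _welch_arrays(
    a: np.ndarray, b: np.ndarray, axis: int = -1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    na, nb = a.shape[axis], b.shape[axis]
    ma, mb = a.mean(axis=axis), b.mean(axis=axis)
    va, vb = a.var(axis=axis, ddof=1), b.var(axis=axis, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se2 > 0, (ma - mb) / np.sqrt(np.where(se2 > 0, se2, 1.0)), 0.0)
        df = np.where(
            se2 > 0,
            se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)),
            1.0,
        )
    zero = se2 == 0
    equal = zero & np.isclose(ma, mb)
    with np.errstate(invalid="ignore"):
        t = np.where(equal, 0.0, np.where(zero, np.inf * np.sign(ma - mb), t))
    p = np.where(zero, np.where(equal, 1.0, 0.0), 2 * stats.t.sf(np.abs(t), df))
    return t, df, p


def welch_test(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns ``(t, df, p)`` with Welch-Satterthwaite degrees of freedom
    and a two-sided p-value. Both groups need at least two values. When
    both variances are zero and the means agree, ``(0, df, 1)`` is
    returned by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    t, df, p = _welch_arrays(a[None, :], b[None, :])
    return float(t[0]), float(df[0]), float(p[0])


# ---------------------------------------------------------------------------
# Differential calling

def differential_table(
    matrix: NormalizedMatrix,
    params: AnalysisParams = AnalysisParams(),
    design: ArrayDesign | None = None,
) -> pd.DataFrame:
    """Per-probe fold change, Welch statistic and direction call.

    ``direction`` is ``hyper`` when fc >= fc_cut and p < alpha, ``hypo``
    when fc <= 1/fc_cut and p < alpha, else ``ns``. Fold changes are on
    the linear ratio scale; with ``params.log_scale`` the Welch test runs
    on log2 ratios instead (fold cut unchanged).
    """
    tumor_cols = matrix.samples_in("tumor")
    control_cols = matrix.samples_in("control")
    if len(tumor_cols) < 2 or len(control_cols) < 2:
        raise ValueError("need >= 2 samples per biological group")
    T = matrix.ratios[tumor_cols].to_numpy(float)
    C = matrix.ratios[control_cols].to_numpy(float)
    mean_t, mean_c = T.mean(axis=1), C.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_t / mean_c
    if params.log_scale:
        t, df, p = _welch_arrays(np.log2(T), np.log2(C))
    else:
        t, df, p = _welch_arrays(T, C)
    direction = np.where(
        (p < params.alpha) & (fc >= params.fc_cut),
        "hyper",
        np.where((p < params.alpha) & (fc <= 1 / params.fc_cut), "hypo", "ns"),
    )
    gene_map = {}
    if design is not None:
        gene_map = {pr.probe_id: ",".join(pr.gene_ids) for pr in design.probes}
    out = pd.DataFrame(
        {
            "probe_id": matrix.ratios.index,
            "gene_ids": [gene_map.get(pid, "") for pid in matrix.ratios.index],
            "mean_tumor": mean_t,
            "mean_control": mean_c,
            "fc": fc,
            "t": t,
            "df": df,
            "p": p,
            "direction": direction,
        }
    ).reset_index(drop=True)
    return out


def differential_probes(
    matrix: NormalizedMatrix,
    params: AnalysisParams = AnalysisParams(),
    design: ArrayDesign | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hypo- and hypermethylated probe lists, each sorted by p-value."""
    table = differential_table(matrix, params, design)
    hypo = table[table["direction"] == "hypo"].sort_values("p").reset_index(drop=True)
    hyper = table[table["direction"] == "hyper"].sort_values("p").reset_index(drop=True)
    return hypo, hyper


def probe_to_gene(diff_table: pd.DataFrame, design: ArrayDesign) -> pd.DataFrame:
    """Gene-level summary of significant probes.

    Every significant probe row is preserved; a gene's ``gene_direction``
    is the probe direction when unanimous, otherwise ``mixed``.
    """
    probe_genes = {p.probe_id: p.gene_ids for p in design.probes}
    rows = []
    for r in diff_table.itertuples():
        if r.direction == "ns":
            continue
        for gid in probe_genes.get(r.probe_id, ()):
            rows.append({"gene_id": gid, "probe_id": r.probe_id, "direction": r.direction,
                         "fc": r.fc, "p": r.p})
    if not rows:
        return pd.DataFrame(columns=["gene_id", "probe_id", "direction", "fc", "p", "gene_direction"])
    df = pd.DataFrame(rows)
    summary = df.groupby("gene_id")["direction"].agg(
        lambda d: d.iloc[0] if d.nunique() == 1 else "mixed"
    )
    df["gene_direction"] = df["gene_id"].map(summary)
    return df.sort_values(["gene_id", "probe_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Median classes, PCA, enrichment

def median_classes(
    gene_signals: pd.Series, median_fold: float = 2.0
) -> tuple[list[str], list[str]]:
    """Split genes into lower/higher methylation classes around the median.

    ``gene_signals`` holds one mean control-sample signal per gene.
    ``higher`` collects genes at or above ``median_fold`` times the
    median, ``lower`` those at or below median / ``median_fold``
    (boundaries included).
    """
    if len(gene_signals) < 2:
        raise ValueError("need >= 2 genes")
    med = float(gene_signals.median())
    higher = gene_signals[gene_signals >= median_fold * med].index.tolist()
    lower = gene_signals[gene_signals <= med / median_fold].index.tolist()
    return sorted(lower), sorted(higher)


def pca_scores(matrix: pd.DataFrame, n_components: int | None = None) -> pd.DataFrame:
    """Sample scores from a PCA of a samples x probes matrix.

    Columns (probes) are mean-centered, not scaled. Scores come from the
    singular value decomposition with a deterministic sign convention:
    each component's largest-magnitude probe loading is made positive.
    Zero total variance yields all-zero scores.
    """
    X = matrix.to_numpy(float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 probes")
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        k = n_components or min(X.shape)
        return pd.DataFrame(
            np.zeros((X.shape[0], k)), index=matrix.index, columns=[f"PC{i+1}" for i in range(k)]
        )
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for j in range(Vt.shape[0]):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U * S
    if n_components is not None:
        scores = scores[:, :n_components]
    return pd.DataFrame(
        scores, index=matrix.index, columns=[f"PC{i+1}" for i in range(scores.shape[1])]
    )


def term_enrichment(
    gene_list: list[str],
    universe: list[str],
    gene_terms: dict[str, set[str]] | pd.DataFrame,
    params: AnalysisParams = AnalysisParams(),
) -> pd.DataFrame:
    """Hypergeometric over-representation of terms in a gene list.

    For each term with K annotated genes in a universe of N, the
    upper-tail probability of observing >= k hits in a list of n is
    computed, then Benjamini-Hochberg adjusted across terms.
    ``gene_terms`` maps gene_id -> set of term ids (or a two-column
    ``gene_id``/``term_id`` frame).
    """
    if not gene_list or not universe:
        raise ValueError("gene list and universe must be non-empty")
    uni = set(universe)
    sel = set(gene_list)
    if not sel <= uni:
        raise ValueError("gene_list must be a subset of universe")
    if isinstance(gene_terms, pd.DataFrame):
        mapping: dict[str, set[str]] = {}
        for r in gene_terms.itertuples():
            mapping.setdefault(str(r.gene_id), set()).add(str(r.term_id))
        gene_terms = mapping
    term_genes: dict[str, set[str]] = {}
    for gid in uni:
        for term in gene_terms.get(gid, ()):
            term_genes.setdefault(term, set()).add(gid)
    N, n = len(uni), len(sel)
    rows = []
    for term, genes in sorted(term_genes.items()):
        K = len(genes)
        k = len(genes & sel)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df["significant"] = df["q"] < params.enrichment_fdr
        df = df.sort_values("p").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Expression overlap

def expression_overlap(
    gene_methylation: pd.DataFrame,
    expression: pd.DataFrame,
    design: ArrayDesign,
    per_gene_islands: dict[str, list] | None = None,
) -> tuple[dict[str, int | float], pd.DataFrame]:
    """Intersect differential methylation with an expression gene list.

    The funnel counts genes with significant expression change, those
    with a promoter CGI, those represented by at least one probe on the
    array, and those also significant for methylation; the concordance
    table joins per-gene expression direction with per-probe methylation
    direction. ``expression`` needs ``gene_id`` and ``direction``
    (up/down) columns.
    """
    expr_genes = list(dict.fromkeys(expression["gene_id"]))
    if per_gene_islands is None:
        with_cgi = expr_genes
    else:
        with_cgi = [g for g in expr_genes if per_gene_islands.get(g)]
    array_genes = {g for p in design.probes for g in p.gene_ids}
    on_array = [g for g in with_cgi if g in array_genes]
    meth_sig = (
        set(gene_methylation["gene_id"]) if len(gene_methylation) else set()
    )
    both = [g for g in on_array if g in meth_sig]
    funnel = {
        "expression_significant": len(expr_genes),
        "with_promoter_cgi": len(with_cgi),
        "on_array": len(on_array),
        "both_significant": len(both),
        "percent_concordant": 100.0 * len(both) / len(on_array) if on_array else 0.0,
    }
    expr_dir = expression.drop_duplicates("gene_id").set_index("gene_id")["direction"]
    rows = gene_methylation[gene_methylation["gene_id"].isin(both)].copy()
    if len(rows):
        rows["expression"] = rows["gene_id"].map(expr_dir)
        rows = rows.rename(columns={"direction": "methylation"})
    return funnel, rows.reset_index(drop=True)


# ---------------------------------------------------------------------------
# End-to-end convenience

def run_analysis(
    channels: pd.DataFrame,
    params: AnalysisParams = AnalysisParams(),
    design: ArrayDesign | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Ratios -> normalization -> filters -> differential calls."""
    groups = _groups_of(channels)
    raw = compute_ratios(channels)
    matrix = normalize_to_control(raw, groups)
    filtered, audit = filter_probes(matrix, channels, params)
    table = differential_table(filtered, params, design)
    hypo = table[table["direction"] == "hypo"].sort_values("p").reset_index(drop=True)
    hyper = table[table["direction"] == "hyper"].sort_values("p").reset_index(drop=True)
    result = {
        "matrix": filtered,
        "audit": audit,
        "table": table,
        "hypo": hypo,
        "hyper": hyper,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        filtered.ratios.to_csv(out_dir / "normalized_matrix.tsv", sep="\t")
        (out_dir / "audit.json").write_text(json.dumps(audit, indent=2))
        table.to_csv(out_dir / "differential_table.tsv", sep="\t", index=False)
        hypo.to_csv(out_dir / "hypo_probes.tsv", sep="\t", index=False)
        hyper.to_csv(out_dir / "hyper_probes.tsv", sep="\t", index=False)
    return result
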