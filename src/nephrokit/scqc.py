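"""Single-cell QC, normalization, cell-cycle scoring and variable-gene filters.

The pipeline mirrors a plate-based (Sort-seq) UMI workflow:

1. mitochondrial fraction is computed on the full matrix, mitochondrial
   genes are then removed, and per-cell transcript totals are taken on the
   mito-free matrix; cells exceeding 40% mitochondrial transcripts or with
   fewer than 1000 unique transcripts are excluded;
2. lowly expressed genes are dropped (kept only with >= 5 expressing cells
   and >= 2 cells carrying >= 2 transcripts);
3. counts are log-normalized to 10,000 transcripts per cell;
4. per-cell S and G2M module scores are computed from known marker sets
   (marker mean minus expression-bin-matched control mean), every gene is
   correlated with both scores, and data-driven cutoffs

       s_cut   = max( med(S_S)   - med(S_G2M), Q25(S_S) )
       g2m_cut = max( med(G2M_G2M) - med(G2M_S), Q25(G2M_G2M) )

   (S_S = correlations of known S genes with the S score, etc.) flag
   cycle-correlated genes, which are excluded from variable genes along with
   the known markers themselves;
5. profile-specific blacklists (RP-prefixed symbols, heat-shock and
   ribosomal gene lists, chromosome-Y genes, XIST/TSIX, mitochondrial
   pseudogenes) further prune the variable-gene list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

S_CUT_KEY = "s_cut"
G2M_CUT_KEY = "g2m_cut"


@dataclass
class CountMatrix:
    """Integer gene x cell UMI counts with per-gene annotations.

    ``genes`` is a DataFrame indexed by gene identifier with columns
    ``symbol``, ``chromosome`` and ``is_mito``; ``cells`` the barcode list;
    ``counts`` a dense (n_genes, n_cells) integer array.
    """

    genes: pd.DataFrame
    cells: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_float = np.asarray(self.counts, dtype=float)
            if np.any(as_float != np.round(as_float)) or np.any(~np.isfinite(as_float)):
                raise ValidationError("count matrix entries must be integers")
            self.counts = as_float.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValidationError("count matrix entries must be non-negative")
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.genes.index.duplicated().any():
            raise ValidationError("duplicate gene identifiers")
        if len(set(self.cells)) != len(self.cells):
            raise ValidationError("duplicate cell barcodes")
        for col, default in (("symbol", self.genes.index), ("chromosome", ""), ("is_mito", False)):
            if col not in self.genes.columns:
                self.genes = self.genes.assign(**{col: default})
        self.genes["is_mito"] = self.genes["is_mito"].astype(bool)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def subset(self, gene_mask: np.ndarray | None = None, cell_mask: np.ndarray | None = None) -> "CountMatrix":
        g = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask, bool)
        c = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask, bool)
        return CountMatrix(self.genes.loc[g].copy(), [b for b, k in zip(self.cells, c) if k], self.counts[np.ix_(g, c)])


@dataclass
class CutoffPair:
    """Data-driven correlation cutoffs for calling cycle-associated genes."""

    s_cut: float
    g2m_cut: float


@dataclass
class QCReport:
    """Per-cell QC table plus the per-gene expression-filter table."""

    cells: pd.DataFrame
    genes: pd.DataFrame | None = None


def compute_qc(
    counts: CountMatrix, max_mito: float = 0.40, min_transcripts: int = 1000
) -> tuple[pd.DataFrame, CountMatrix]:
    """Cell-level QC: mito-fraction and transcript-total filters.

    Mito fraction uses the full matrix; mitochondrial genes are then removed
    and transcript totals taken on the mito-free matrix. A cell passes iff
    mito fraction <= *max_mito* (strictly exceeding fails) and total >=
    *min_transcripts*. Both rules are evaluated independently and reported.

    Returns the per-cell report (``cell``, ``mito_fraction``,
    ``total_transcripts``, ``fail_mito``, ``fail_min_transcripts``, ``pass``)
    and the filtered matrix (mito genes and failing cells removed).
    """
    if counts.n_genes == 0 or counts.n_cells == 0:
        raise ValidationError("empty count matrix")
    mito_mask = counts.genes["is_mito"].to_numpy()
    grand_total = counts.counts.sum(axis=0).astype(float)
    mito_total = counts.counts[mito_mask].sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        mito_frac = np.where(grand_total > 0, mito_total / np.maximum(grand_total, 1), 0.0)
    nonmito = counts.subset(gene_mask=~mito_mask)
    totals = nonmito.counts.sum(axis=0)
    fail_mito = mito_frac > max_mito
    fail_depth = totals < min_transcripts
    report = pd.DataFrame(
        {
            "cell": counts.cells,
            "mito_fraction": mito_frac,
            "total_transcripts": totals,
            "fail_mito": fail_mito,
            "fail_min_transcripts": fail_depth,
            "pass": ~(fail_mito | fail_depth),
        }
    )
    filtered = nonmito.subset(cell_mask=report["pass"].to_numpy())
    return report, filtered


def filter_genes(
    counts: CountMatrix, min_cells: int = 5, min_cells_ge2: int = 2
) -> tuple[pd.DataFrame, CountMatrix]:
    """Low-expression gene filter, applied after cell filtering.

    A gene is kept iff it is expressed (count >= 1) in at least *min_cells*
    cells AND has at least *min_cells_ge2* cells with count >= 2.
    """
    n_expr = (counts.counts >= 1).sum(axis=1)
    n_ge2 = (counts.counts >= 2).sum(axis=1)
    keep = (n_expr >= min_cells) & (n_ge2 >= min_cells_ge2)
    report = pd.DataFrame(
        {"gene": counts.genes.index, "n_cells_expressing": n_expr, "n_cells_ge2": n_ge2, "keep": keep}
    ).set_index("gene")
    return report, counts.subset(gene_mask=keep)


def lognormalize(counts: CountMatrix, scale: int = 10000) -> pd.DataFrame:
    """Log-normalize to *scale* transcripts per cell: ``ln(1 + scale*x/total)``.

    Returns a float DataFrame (genes x cells). Zero-total cells are a QC
    violation and raise.
    """
    totals = counts.counts.sum(axis=0).astype(float)
    if np.any(totals == 0):
        raise ValidationError("zero-total cell encountered; run compute_qc first")
    norm = np.log1p(scale * counts.counts / totals)
    return pd.DataFrame(norm, index=counts.genes.index, columns=counts.cells)


def _module_score(
    norm: pd.DataFrame, markers: list[str], n_bins: int, n_ctrl: int, rng: np.random.Generator
) -> np.ndarray:
    """Marker-set module score: marker mean minus bin-matched control mean."""
    present = [g for g in markers if g in norm.index]
    if not present:
        raise ValidationError("none of the marker genes are present in the matrix")
    avg = norm.mean(axis=1)
    # rank-based binning keeps bins near-equal-sized regardless of the
    # expression distribution
    order = avg.rank(method="first") - 1
    bins = np.floor(order / len(avg) * n_bins).astype(int).clip(0, n_bins - 1)
    bins = pd.Series(bins, index=norm.index)
    controls: list[str] = []
    for g in present:
        pool = bins.index[bins.to_numpy() == bins[g]].tolist()
        k = min(n_ctrl, len(pool))
        controls.extend(rng.choice(pool, size=k, replace=False))
    marker_mean = norm.loc[present].mean(axis=0).to_numpy()
    ctrl_mean = norm.loc[controls].mean(axis=0).to_numpy()
    return marker_mean - ctrl_mean


def cycle_score(
    norm: pd.DataFrame,
    s_genes: list[str],
    g2m_genes: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell S and G2M module scores (columns ``s_score``, ``g2m_score``).

    Controls are sampled without replacement, per marker gene, from the
    marker's average-expression bin (*n_bins* bins over all genes, *n_ctrl*
    controls per marker), with a seeded generator for reproducibility.
    """
    rng = np.random.default_rng(seed)
    s = _module_score(norm, list(s_genes), n_bins, n_ctrl, rng)
    g2m = _module_score(norm, list(g2m_genes), n_bins, n_ctrl, rng)
    return pd.DataFrame({"s_score": s, "g2m_score": g2m}, index=norm.columns)


def gene_score_correlations(norm: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of every gene with the S and G2M scores.

    Constant genes (or a constant score) get correlation 0 and are flagged in
    the ``constant`` column.
    """
    if norm.shape[1] < 3:
        raise ValidationError("need at least 3 cells to correlate")
    x = norm.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    xs = xc.std(axis=1)
    out = {}
    for col in ("s_score", "g2m_score"):
        y = scores[col].to_numpy(dtype=float)
        yc = y - y.mean()
        ys = yc.std()
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc @ yc) / (norm.shape[1] * xs * ys)
        out["r_s" if col == "s_score" else "r_g2m"] = np.where((xs == 0) | (ys == 0), 0.0, r)
    df = pd.DataFrame(out, index=norm.index)
    df["constant"] = xs == 0
    return df


def cycle_cutoffs(
    correlations: pd.DataFrame,
    s_genes: list[str],
    g2m_genes: list[str],
    quantile_method: str = "linear",
) -> CutoffPair:
    """Data-driven cutoffs from known-marker correlation distributions.

    ``s_cut = max(med(S_S) - med(S_G2M), Q25(S_S))`` where S_S / S_G2M are
    the correlations of the known S genes with the S / G2M scores; the G2M
    cutoff is the mirror formula. Quantiles use linear (type-7)
    interpolation by default; the convention is switchable because it
    changes the cutoff.
    """
    s_present = [g for g in s_genes if g in correlations.index]
    g2m_present = [g for g in g2m_genes if g in correlations.index]
    if not s_present or not g2m_present:
        raise ValidationError("no known marker genes with defined correlations")
    s_s = correlations.loc[s_present, "r_s"].to_numpy()
    s_g2m = correlations.loc[s_present, "r_g2m"].to_numpy()
    g2m_g2m = correlations.loc[g2m_present, "r_g2m"].to_numpy()
    g2m_s = correlations.loc[g2m_present, "r_s"].to_numpy()
    q = lambda v: float(np.quantile(v, 0.25, method=quantile_method))  # noqa: E731
    s_cut = max(float(np.median(s_s) - np.median(s_g2m)), q(s_s))
    g2m_cut = max(float(np.median(g2m_g2m) - np.median(g2m_s)), q(g2m_g2m))
    return CutoffPair(s_cut, g2m_cut)


def flag_cycle_genes(
    correlations: pd.DataFrame,
    cutoffs: CutoffPair,
    known_markers: list[str] = (),
) -> pd.Series:
    """Boolean per-gene flag: cycle-associated, hence excluded from variable genes.

    A gene is flagged iff its correlation with either score strictly exceeds
    the respective cutoff; known markers are flagged unconditionally.
    """
    flagged = (correlations["r_s"] > cutoffs.s_cut) | (correlations["r_g2m"] > cutoffs.g2m_cut)
    flagged.loc[flagged.index.intersection(list(known_markers))] = True
    flagged.name = "cycle_gene"
    return flagged


@dataclass
class Blacklists:
    """Plain-text gene lists used by the variable-gene filters."""

    heatshock: list[str] = field(default_factory=list)  # e.g. GO:0006986 members
    ribosome: list[str] = field(default_factory=list)  # e.g. GO:0022626 members
    mito_pseudogenes: list[str] = field(default_factory=list)
    sex_exclusive: list[str] = field(default_factory=lambda: ["XIST", "TSIX"])


def blacklist_variable_genes(
    genes: list[str],
    cycle_genes: list[str],
    blacklists: Blacklists,
    profile: str = "fig3",
    annotations: pd.DataFrame | None = None,
) -> list[str]:
    """Prune a variable-gene list according to a filter profile.

    ``fig3`` removes mitochondrial pseudogenes, cycle-associated genes and
    RP-prefixed symbols. ``early_late`` additionally removes heat-shock
    genes, ribosomal-protein genes, chromosome-Y genes (from *annotations*)
    and the female-exclusive XIST/TSIX. Symbols are looked up in
    *annotations* when provided, else the identifiers themselves are treated
    as symbols.
    """
    if profile not in ("fig3", "early_late"):
        raise ConfigurationError(f"unknown variable-gene filter profile: {profile!r}")
    drop: set[str] = set(blacklists.mito_pseudogenes) | set(cycle_genes)
    symbols = {}
    chrom = {}
    for g in genes:
        if annotations is not None and g in annotations.index:
            symbols[g] = str(annotations.loc[g, "symbol"])
            chrom[g] = str(annotations.loc[g, "chromosome"])
        else:
            symbols[g] = g
            chrom[g] = ""
    drop |= {g for g in genes if symbols[g].startswith("RP")}
    if profile == "early_late":
        drop |= set(blacklists.heatshock) | set(blacklists.ribosome) | set(blacklists.sex_exclusive)
        drop |= {g for g in genes if symbols[g] in set(blacklists.heatshock) | set(blacklists.ribosome) | set(blacklists.sex_exclusive)}
        drop |= {g for g in genes if chrom[g].removeprefix("chr") == "Y"}
    return [g for g in genes if g not in drop]
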