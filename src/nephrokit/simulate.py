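"""Seeded generators for every analysis stage's inputs.

The study's sequencing data are controlled-access, so each pipeline stage is
exercised on synthetic inputs carrying the statistical structure the stage
assumes, together with a truth object sufficient to score the stage's output
without re-deriving anything:

* reference-like mutational signatures (sparse, peaked 96-channel
  probability columns, pairwise cosine < 0.9) and catalogs mixed from them,
  optionally with channel-wise Poisson noise;
* negative-binomial gene x cell count matrices with planted cluster-marker
  blocks, S/G2M-phase-responsive gene blocks, a mitochondrial gene block
  with a configurable share of high-mito cells, and log-normal library
  sizes with a configurable share of low-depth cells;
* candidate variant tables with a configurable number of records violating
  each hard-filter rule in isolation;
* drug-screen plates generated from known 4PL curves with multiplicative
  log-normal noise, DMSO vehicle wells at 100% viability and staurosporine
  positive-control wells near zero.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .doseresponse import four_pl
from .errors import GenerationError, ValidationError
from .scqc import CountMatrix
from .signatures import MutationalProfile, SignatureSet
from .variants import VariantRecord


# ---------------------------------------------------------------------------
# signatures and catalogs

def gen_signature_set(
    n_signatures: int,
    peaked_channels: int = 4,
    seed: int = 0,
    max_cosine: float = 0.9,
    max_retries: int = 100,
) -> SignatureSet:
    """Random signature columns emulating the structure of real SBS references.

    The first column (named SBS1) is moderately peaked; the second (SBS5) is
    near-flat, like the real clock-like signatures; the remaining columns
    are sparse Dirichlet draws with *peaked_channels* strongly boosted
    channels carrying most of the probability mass, mimicking the peaky
    structure of real mutational processes so that greedy selection is
    neither trivial nor impossible. All columns are non-negative and sum
    to 1. The whole set is regenerated until all pairwise cosines fall
    below *max_cosine*; the first two columns serve as the forced
    clock-like signatures.
    """
    if n_signatures < 2:
        raise ValidationError("need at least 2 signatures")
    if not 1 <= peaked_channels <= 96:
        raise ValidationError("peaked_channels must be in [1, 96]")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        cols = []
        for j in range(n_signatures):
            if j == 0:  # moderately peaked clock signature
                w = rng.gamma(1.0, 1.0, size=96)
                peaks = rng.choice(96, size=peaked_channels, replace=False)
                w[peaks] *= rng.uniform(4.0, 10.0, size=peaked_channels)
            elif j == 1:  # flat clock signature
                w = rng.gamma(5.0, 1.0, size=96)
            else:  # sparse, strongly peaked
                w = rng.gamma(0.01, 1.0, size=96)
                peaks = rng.choice(96, size=peaked_channels, replace=False)
                w[peaks] *= rng.uniform(200.0, 600.0, size=peaked_channels)
            cols.append(w / w.sum())
        m = np.column_stack(cols)
        norms = np.linalg.norm(m, axis=0)
        cos = (m.T @ m) / np.outer(norms, norms)
        np.fill_diagonal(cos, 0.0)
        if cos.max() < max_cosine:
            names = ["SBS1", "SBS5"]
            k = 2
            while len(names) < n_signatures:
                if k not in (1, 5):
                    names.append(f"SBS{k}")
                k += 1
            return SignatureSet(names[:n_signatures], m, forced=["SBS1", "SBS5"])
    raise GenerationError(
        f"could not draw {n_signatures} signatures with pairwise cosine < {max_cosine}; try fewer signatures"
    )


def gen_catalog(
    signatures: SignatureSet,
    exposures: dict[str, Sequence[float]],
    total_mutations: float = 3000,
    noise: str = "poisson",
    seed: int = 0,
) -> dict[str, MutationalProfile]:
    """Catalogs as (possibly Poisson-noised) signature mixtures.

    *exposures* maps sample name to per-signature mixture weights
    (non-negative, summing to 1). With ``noise="none"`` the profile is
    exactly ``total_mutations * (S @ w)`` (real-valued); with
    ``noise="poisson"`` each channel is an independent Poisson draw of that
    mean.
    """
    if noise not in ("none", "poisson"):
        raise ValidationError(f"unknown noise model: {noise!r}")
    rng = np.random.default_rng(seed)
    out = {}
    for sample, w in exposures.items():
        w = np.asarray(w, dtype=float)
        if w.shape != (len(signatures.names),):
            raise ValidationError(f"sample {sample!r}: weight length != number of signatures")
        if np.any(w < 0):
            raise ValidationError(f"sample {sample!r}: negative mixture weight")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError(f"sample {sample!r}: weights must sum to 1")
        mean = total_mutations * (signatures.matrix @ w)
        counts = mean if noise == "none" else rng.poisson(mean).astype(float)
        out[sample] = MutationalProfile(sample, counts)
    return out


# ---------------------------------------------------------------------------
# single-cell counts

@dataclass
class ScTruth:
    """Ground truth for a generated count matrix."""

    phase: pd.Series  # per cell: G1 | S | G2M
    cluster: pd.Series  # per cell
    organoid: pd.Series  # per cell
    s_genes: list[str]
    g2m_genes: list[str]
    s_correlated: list[str]  # cycle-responsive genes NOT in the known marker lists
    g2m_correlated: list[str]
    cluster_markers: dict[str, list[str]]
    mito_genes: list[str]
    high_mito_cells: list[str]
    low_depth_cells: list[str]

    @property
    def expected_fail_cells(self) -> set[str]:
        return set(self.high_mito_cells) | set(self.low_depth_cells)


def gen_sc_counts(
    n_genes: int = 1500,
    n_cells: int = 360,
    n_clusters: int = 3,
    frac_mito_genes: float = 0.02,
    cycle_fraction: float = 0.5,
    marker_fold: float = 3.0,
    cycle_fold: float = 8.0,
    share_high_mito: float = 0.05,
    share_low_depth: float = 0.05,
    n_block_genes: int = 40,
    nb_size: float = 2.0,
    seed: int = 0,
) -> tuple[CountMatrix, ScTruth]:
    """Negative-binomial counts with planted phase, cluster and QC structure.

    Gene blocks (each *n_block_genes* genes): known S markers, known G2M
    markers, an extra cycle-responsive block per phase (for testing
    correlation-based flagging), and one marker block per cluster elevated
    *marker_fold*-fold in that cluster's cells. Cycle-responsive genes are
    elevated *cycle_fold*-fold in their own phase and by the square root of
    that in the other cycling phase (phases share a proliferation
    programme); the *known* marker blocks respond heterogeneously (per-gene
    fold log-uniform between ``cycle_fold**0.25`` and ``cycle_fold``) the
    way canonical marker lists do in real data, while the extra blocks
    respond at full strength. ``marker_fold=1`` plants no cluster
    structure and ``cycle_fold=1`` no cycle structure (null data for
    calibration). High-mito cells target a ~60% mitochondrial fraction (vs
    2-15% baseline); low-depth cells draw 300-700 non-mito transcripts
    against a log-normal baseline centred at ~5000, so QC at the 40%/1000
    thresholds separates the planted sets cleanly. Dispersion is fixed
    (size 2) for realistic overdispersion without extra knobs.
    """
    if marker_fold < 1 or cycle_fold < 1:
        raise ValidationError("marker_fold and cycle_fold must be >= 1")
    n_mito = max(2, int(round(frac_mito_genes * n_genes)))
    needed = 4 * n_block_genes + n_clusters * n_block_genes + n_mito
    if needed > n_genes:
        raise ValidationError(f"gene blocks need {needed} genes but n_genes={n_genes}")
    rng = np.random.default_rng(seed)

    mito_genes = [f"MT-{i + 1}" for i in range(n_mito)]
    n_rest = n_genes - n_mito
    gene_ids = [f"G{i + 1:05d}" for i in range(n_rest)]
    pos = 0

    def take(k: int) -> list[str]:
        nonlocal pos
        block = gene_ids[pos : pos + k]
        pos += k
        return block

    s_genes = take(n_block_genes)
    g2m_genes = take(n_block_genes)
    s_corr = take(n_block_genes)
    g2m_corr = take(n_block_genes)
    cluster_markers = {f"c{k}": take(n_block_genes) for k in range(n_clusters)}

    all_genes = gene_ids + mito_genes
    chrom_pool = [str(i) for i in range(1, 23)] + ["X", "Y"]
    chromosomes = list(rng.choice(chrom_pool, size=n_rest)) + ["MT"] * n_mito
    genes = pd.DataFrame(
        {"symbol": all_genes, "chromosome": chromosomes, "is_mito": [False] * n_rest + [True] * n_mito},
        index=pd.Index(all_genes, name="gene"),
    )

    cells = [f"cell{i + 1:04d}" for i in range(n_cells)]
    phase = rng.choice(["S", "G2M", "G1"], size=n_cells, p=[cycle_fraction / 2, cycle_fraction / 2, 1 - cycle_fraction])
    cluster = np.array([f"c{k}" for k in rng.integers(0, n_clusters, size=n_cells)])
    high_mito = rng.random(n_cells) < share_high_mito
    low_depth = (~high_mito) & (rng.random(n_cells) < share_low_depth)

    # per-cell targets: non-mito library size and mito fraction
    lib = np.exp(rng.normal(np.log(5000.0), 0.3, size=n_cells)).clip(2000, None)
    lib[low_depth] = rng.uniform(300, 700, size=int(low_depth.sum()))
    lib[high_mito] = rng.uniform(3000, 6000, size=int(high_mito.sum()))
    mito_frac = rng.uniform(0.02, 0.15, size=n_cells)
    mito_frac[high_mito] = rng.uniform(0.55, 0.70, size=int(high_mito.sum()))

    # base relative expression, log-normal across genes
    base = np.exp(rng.normal(0.0, 1.0, size=n_genes))
    idx = {g: i for i, g in enumerate(all_genes)}
    mult = np.ones((n_genes, n_cells))
    s_cells = np.flatnonzero(phase == "S")
    g2m_cells = np.flatnonzero(phase == "G2M")
    if cycle_fold > 1:
        for own, other, markers, extras in (
            (s_cells, g2m_cells, s_genes, s_corr),
            (g2m_cells, s_cells, g2m_genes, g2m_corr),
        ):
            m_rows = [idx[g] for g in markers]
            m_fold = np.exp(rng.uniform(0.25 * np.log(cycle_fold), np.log(cycle_fold), size=len(m_rows)))
            mult[np.ix_(m_rows, own)] *= m_fold[:, None]
            mult[np.ix_(m_rows, other)] *= np.sqrt(m_fold)[:, None]
            e_rows = [idx[g] for g in extras]
            mult[np.ix_(e_rows, own)] *= cycle_fold
            mult[np.ix_(e_rows, other)] *= np.sqrt(cycle_fold)
    if marker_fold > 1:
        for cname, block in cluster_markers.items():
            rows = [idx[g] for g in block]
            mult[np.ix_(rows, np.flatnonzero(cluster == cname))] *= marker_fold

    mito_mask = genes["is_mito"].to_numpy()
    weights = base[:, None] * mult
    w_nonmito = weights[~mito_mask]
    w_nonmito = w_nonmito / w_nonmito.sum(axis=0, keepdims=True)
    w_mito = weights[mito_mask]
    w_mito = w_mito / w_mito.sum(axis=0, keepdims=True)
    mean = np.empty_like(weights)
    mean[~mito_mask] = w_nonmito * lib
    mean[mito_mask] = w_mito * (lib * mito_frac / (1.0 - mito_frac))

    # NB(mean mu, size r): p = r / (r + mu)
    p = nb_size / (nb_size + mean)
    counts = rng.negative_binomial(nb_size, p)

    cm = CountMatrix(genes, cells, counts)
    truth = ScTruth(
        phase=pd.Series(phase, index=cells, name="phase"),
        cluster=pd.Series(cluster, index=cells, name="cluster"),
        organoid=pd.Series(["org1"] * n_cells, index=cells, name="organoid"),
        s_genes=s_genes,
        g2m_genes=g2m_genes,
        s_correlated=s_corr,
        g2m_correlated=g2m_corr,
        cluster_markers=cluster_markers,
        mito_genes=mito_genes,
        high_mito_cells=[c for c, h in zip(cells, high_mito) if h],
        low_depth_cells=[c for c, l in zip(cells, low_depth) if l],
    )
    return cm, truth


# ---------------------------------------------------------------------------
# variant tables

@dataclass
class VariantTruth:
    """Per-record pass/fail truth and the control-called positions."""

    verdicts: list[bool]
    reasons: list[list[str]]
    control_variants: list[tuple[str, int]] = field(default_factory=list)


def _passing_record(i: int, rng: np.random.Generator, matched_normal: bool, vtype: str = "snv") -> VariantRecord:
    chrom = str(1 + (i % 22))
    pos = 1_000_000 + 10_000 * i
    ref, alt = ("A", "G") if vtype == "snv" else ("AT", "A")
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        tumour_depth=int(rng.integers(30, 80)),
        tumour_vaf=float(rng.uniform(0.3, 0.6)),
        site_qual=float(rng.uniform(400, 900)),
        mq=60.0,
        tumour_gq=99.0,
        normal_depth=int(rng.integers(30, 80)) if matched_normal else None,
        normal_alt_reads=0 if matched_normal else None,
        normal_gq=99.0 if matched_normal else None,
        normal_nonref_gt=False if matched_normal else None,
        dbsnp=False,
        gene=f"GENE{i}",
        annotation_class="missense",
    )


def gen_variant_table(
    n_pass: int = 10,
    violations: dict[str, int] | None = None,
    matched_normal: bool = True,
    seed: int = 0,
) -> tuple[list[VariantRecord], VariantTruth]:
    """Candidate records: *n_pass* clean calls plus single-rule violators.

    *violations* maps rule name (``normal_evidence, dbsnp, depth, vaf,
    site_qual, mq, autosome, indel_proximity``) to the number of records
    violating exactly that rule. Records are spaced 10 kb apart so the
    proximity rule only fires where planted; one control-called variant is
    emitted per proximity violator.
    """
    violations = dict(violations or {})
    rng = np.random.default_rng(seed)
    records: list[VariantRecord] = []
    reasons: list[list[str]] = []
    controls: list[tuple[str, int]] = []
    i = 0
    for _ in range(n_pass):
        vtype = "indel" if (matched_normal and i % 4 == 3) else "snv"
        records.append(_passing_record(i, rng, matched_normal, vtype))
        reasons.append([])
        i += 1
    for rule, count in sorted(violations.items()):
        for _ in range(count):
            rec = _passing_record(i, rng, matched_normal)
            if rule == "normal_evidence":
                if not matched_normal:
                    raise ValidationError("normal_evidence violations require matched_normal=True")
                rec.normal_alt_reads = int(rng.integers(2, 8))
            elif rule == "dbsnp":
                rec.dbsnp = True
            elif rule == "depth":
                rec.tumour_depth = int(rng.integers(1, 10 if matched_normal else 20))
            elif rule == "vaf":
                rec.tumour_vaf = float(rng.uniform(0.01, 0.09))
            elif rule == "site_qual":
                rec.site_qual = float(rng.uniform(10, 99))
            elif rule == "mq":
                rec = _passing_record(i, rng, matched_normal, vtype="indel")
                rec.mq = float(rng.uniform(10, 59))
            elif rule == "autosome":
                rec.chrom = str(rng.choice(["X", "Y"]))
            elif rule == "indel_proximity":
                rec = _passing_record(i, rng, matched_normal, vtype="indel")
                controls.append((rec.chrom, rec.pos + int(rng.integers(1, 100))))
            else:
                raise ValidationError(f"unknown filter rule: {rule!r}")
            records.append(rec)
            reasons.append([rule])
            i += 1
    truth = VariantTruth(verdicts=[not r for r in reasons], reasons=reasons, control_variants=controls)
    return records, truth


# ---------------------------------------------------------------------------
# drug-screen plates

@dataclass
class PlateTruth:
    """True curve parameters and layout of a generated plate."""

    params: dict[str, tuple[float, float, float, float]]  # top, bottom, ic50_nM, hill
    scale: float
    concentrations: np.ndarray


def gen_plate(
    compounds: dict[str, tuple[float, float, float, float]],
    concentrations: Sequence[float] | None = None,
    replicates: int = 4,
    cv: float = 0.1,
    n_dmso: int = 8,
    n_staurosporine: int = 8,
    scale: float = 20000.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, PlateTruth]:
    """One plate of raw luminescence readings from known 4PL curves.

    *compounds* maps name to true (top, bottom, ic50_nM, hill). The default
    grid is six half-log concentrations (10..3.16e3 nM); each
    (compound, concentration) gets *replicates* technical replicate wells.
    Readings are ``scale * viability/100`` times multiplicative log-normal
    noise with coefficient of variation *cv* (``cv=0`` is noise-free).
    DMSO wells sit at 100% viability, staurosporine wells at ~0.5%.
    """
    if concentrations is None:
        concentrations = 10.0 ** np.linspace(1, 3.5, 6)
    conc = np.asarray(list(concentrations), dtype=float)
    if np.any(conc <= 0):
        raise ValidationError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))

    def noisy(v: np.ndarray) -> np.ndarray:
        if cv == 0:
            return np.asarray(v, dtype=float)
        return v * np.exp(rng.normal(-sigma**2 / 2, sigma, size=np.shape(v)))

    rows = []
    well = 0
    for _ in range(n_dmso):
        rows.append(("dmso", np.nan, 1, float(noisy(np.array([100.0]))[0]), "dmso"))
    for _ in range(n_staurosporine):
        rows.append(("staurosporine", np.nan, 1, float(noisy(np.array([0.5]))[0]), "staurosporine"))
    for name in sorted(compounds):
        top, bottom, ic50, hill = compounds[name]
        for c in conc:
            v_true = four_pl(np.array([c]), top, bottom, ic50, hill)[0]
            for rep in range(1, replicates + 1):
                rows.append((name, float(c), rep, float(noisy(np.array([v_true]))[0]), "test"))
    plate = pd.DataFrame(
        [
            {
                "well": f"W{j + 1:03d}",
                "compound": name,
                "concentration_nM": c,
                "replicate": rep,
                "reading": scale * v / 100.0,
                "role": role,
            }
            for j, (name, c, rep, v, role) in enumerate(rows)
        ]
    )
    truth = PlateTruth(params=dict(compounds), scale=scale, concentrations=conc)
    return plate, truth
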