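"""Readers and writers for every external format the pipeline touches.

Formats: 96-channel catalog and signature TSVs (channels in rows, canonical
order enforced on read regardless of input order), gene x cell counts as
MatrixMarket triplets (matrix + gene list + barcode list) or dense TSV, a
VCF 4.2 subset for candidate variants (via cyvcf2), drug-screen plate CSVs,
plain-text gene lists, and JSON run manifests. All dense I/O keeps genes in
rows; MTX is interpreted genes x cells.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from . import __version__
from .channels import CHANNELS, channel_order
from .errors import FormatError, ValidationError
from .scqc import CountMatrix
from .signatures import MutationalProfile, SignatureSet
from .variants import VariantRecord

# ---------------------------------------------------------------------------
# catalogs and signatures

def read_catalog(path: str | Path) -> dict[str, MutationalProfile]:
    """Read a catalog TSV (96 channel rows x >=1 sample columns).

    The first column holds channel labels in either accepted spelling and
    any order; profiles are returned in canonical channel order.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise FormatError(f"{path}: catalog has no sample columns")
    order = channel_order([str(l) for l in df.index])
    out = {}
    for sample in df.columns:
        col = pd.to_numeric(df[sample], errors="coerce").to_numpy()
        if np.any(~np.isfinite(col)):
            row = int(np.flatnonzero(~np.isfinite(col))[0])
            raise ValidationError(f"{path}: non-numeric count at row {df.index[row]!r}, column {sample!r}")
        if np.any(col < 0):
            row = int(np.flatnonzero(col < 0)[0])
            raise ValidationError(f"{path}: negative count at row {df.index[row]!r}, column {sample!r}")
        out[str(sample)] = MutationalProfile(str(sample), col[order])
    return out


def write_catalog(profiles: dict[str, MutationalProfile], path: str | Path) -> None:
    df = pd.DataFrame({s: p.counts for s, p in profiles.items()}, index=list(CHANNELS))
    df.index.name = "channel"
    df.to_csv(path, sep="\t")


def read_signatures(path: str | Path, forced: Sequence[str] = (), normalize: bool = True) -> SignatureSet:
    """Read a signature reference TSV (96 channel rows x K signature columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    order = channel_order([str(l) for l in df.index])
    m = df.to_numpy(dtype=float)[order]
    if np.any(m < 0):
        raise ValidationError(f"{path}: negative signature entry")
    if normalize:
        sums = m.sum(axis=0)
        if np.any(sums <= 0):
            raise ValidationError(f"{path}: all-zero signature column")
        m = m / sums
    return SignatureSet([str(c) for c in df.columns], m, forced=list(forced))


def write_signatures(sigset: SignatureSet, path: str | Path) -> None:
    df = pd.DataFrame(sigset.matrix, index=list(CHANNELS), columns=sigset.names)
    df.index.name = "channel"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# count matrices

def _attach_annotations(genes: pd.DataFrame, annotations: pd.DataFrame | None) -> pd.DataFrame:
    if annotations is None:
        return genes
    joined = genes.join(annotations, how="left", rsuffix="_ann")
    for col in ("symbol", "chromosome", "is_mito"):
        ann_col = f"{col}_ann"
        if ann_col in joined.columns:
            joined[col] = joined[ann_col].combine_first(joined[col]) if col in genes.columns else joined[ann_col]
            joined = joined.drop(columns=ann_col)
        elif col in annotations.columns:
            joined[col] = annotations[col].reindex(joined.index)
    joined["is_mito"] = joined.get("is_mito", False)
    joined["is_mito"] = joined["is_mito"].fillna(False).astype(bool)
    return joined


def read_counts(
    path: str | Path,
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
    annotations_path: str | Path | None = None,
) -> CountMatrix:
    """Read counts from an MTX triplet or a dense TSV (genes in rows).

    ``.mtx`` input requires the gene-list and barcode-list files; a dense
    TSV carries gene ids in the first column and barcodes in the header. An
    optional side table (TSV, columns ``symbol``, ``chromosome``,
    ``is_mito`` indexed by gene) supplies annotations.
    """
    path = Path(path)
    annotations = None
    if annotations_path is not None:
        annotations = pd.read_csv(annotations_path, sep="\t", index_col=0)
    if path.suffix == ".mtx":
        if genes_path is None or barcodes_path is None:
            raise FormatError("MTX input requires gene and barcode list files")
        m = scipy.io.mmread(path)
        m = scipy.sparse.coo_matrix(m)
        gene_ids = [l.strip().split("\t")[0] for l in Path(genes_path).read_text().splitlines() if l.strip()]
        barcodes = [l.strip() for l in Path(barcodes_path).read_text().splitlines() if l.strip()]
        if m.shape[0] != len(gene_ids):
            raise FormatError(
                f"{genes_path}: {len(gene_ids)} gene labels but matrix has {m.shape[0]} rows"
            )
        if m.shape[1] != len(barcodes):
            raise FormatError(
                f"{barcodes_path}: {len(barcodes)} barcodes but matrix has {m.shape[1]} columns"
            )
        data = np.asarray(m.todense())
        genes = pd.DataFrame(index=pd.Index(gene_ids, name="gene"))
        return CountMatrix(_attach_annotations(genes, annotations), barcodes, data)
    df = pd.read_csv(path, sep="\t", index_col=0)
    genes = pd.DataFrame(index=pd.Index([str(g) for g in df.index], name="gene"))
    return CountMatrix(_attach_annotations(genes, annotations), [str(c) for c in df.columns], df.to_numpy())


def write_counts_dense(cm: CountMatrix, path: str | Path) -> None:
    df = pd.DataFrame(cm.counts, index=cm.genes.index, columns=cm.cells)
    df.to_csv(path, sep="\t")


def write_counts_mtx(cm: CountMatrix, matrix_path: str | Path, genes_path: str | Path, barcodes_path: str | Path) -> None:
    scipy.io.mmwrite(str(matrix_path), scipy.sparse.coo_matrix(cm.counts))
    Path(genes_path).write_text("\n".join(cm.genes.index) + "\n")
    Path(barcodes_path).write_text("\n".join(cm.cells) + "\n")


def write_annotations(cm: CountMatrix, path: str | Path) -> None:
    cm.genes.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# variants (VCF 4.2 subset)

VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">
##INFO=<ID=DB,Number=0,Type=Flag,Description="dbSNP membership">
##INFO=<ID=ANN,Number=1,Type=String,Description="Annotation: gene|class">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""


def write_variants(
    records: Sequence[VariantRecord], path: str | Path, matched_normal: bool | None = None
) -> None:
    """Write records as a minimal VCF 4.2 (TUMOR column, NORMAL when present)."""
    if matched_normal is None:
        matched_normal = any(r.has_normal for r in records)
    samples = "TUMOR\tNORMAL" if matched_normal else "TUMOR"
    lines = [VCF_HEADER + f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}"]
    for r in records:
        alt_reads = int(round(r.tumour_vaf * r.tumour_depth))
        info = f"MQ={r.mq:g}"
        if r.dbsnp:
            info += ";DB"
        if r.annotation_class is not None:
            info += f";ANN={r.gene or '.'}|{r.annotation_class}"
        tum = f"0/1:{r.tumour_depth}:{r.tumour_depth - alt_reads},{alt_reads}:{int(r.tumour_gq or 0)}"
        fields = [r.chrom, str(r.pos), ".", r.ref, r.alt, f"{r.site_qual:g}", ".", info, "GT:DP:AD:GQ", tum]
        if matched_normal:
            if not r.has_normal:
                raise ValidationError(f"record {r.chrom}:{r.pos} lacks normal fields")
            gt = "0/1" if r.normal_nonref_gt else "0/0"
            nor = f"{gt}:{r.normal_depth}:{r.normal_depth - (r.normal_alt_reads or 0)},{r.normal_alt_reads or 0}:{int(r.normal_gq or 0)}"
            fields.append(nor)
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_variants(path: str | Path, matched_normal_expected: bool = False) -> list[VariantRecord]:
    """Read candidate calls from a VCF 4.2 subset via cyvcf2.

    One record is emitted per ALT allele. VAF is computed from AD
    (alt / total depth). The first sample column is the tumour, the second
    (when present) the matched normal. Missing required FORMAT fields (DP,
    AD, GQ) raise a format error naming the field and record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    n_samples = len(vcf.samples)
    if n_samples < 1:
        raise FormatError(f"{path}: VCF has no sample columns")
    if matched_normal_expected and n_samples < 2:
        raise FormatError(f"{path}: matched normal expected but VCF has a single sample column")
    records = []
    for line_no, v in enumerate(vcf, start=1):
        fmt = v.FORMAT
        for fieldname in ("DP", "AD", "GQ"):
            if fieldname not in fmt:
                raise FormatError(f"{path}: record {line_no} ({v.CHROM}:{v.POS}) missing FORMAT field {fieldname}")
        depths = v.format("DP")[:, 0]
        ad = v.format("AD")
        gq = v.format("GQ")
        gq = gq[:, 0] if gq.ndim == 2 else gq
        mq = v.INFO.get("MQ")
        ann = v.INFO.get("ANN")
        gene = ann_class = None
        if ann:
            parts = str(ann).split("|")
            gene = parts[0] if parts[0] != "." else None
            ann_class = parts[1] if len(parts) > 1 else None
        gts = v.genotypes  # [allele_a, allele_b, phased]
        for alt_i, alt in enumerate(v.ALT):
            t_dp = int(depths[0])
            t_alt = int(ad[0, alt_i + 1]) if ad.shape[1] > alt_i + 1 else 0
            vaf = t_alt / t_dp if t_dp > 0 else 0.0
            kwargs = {}
            if n_samples >= 2:
                n_gt = gts[1][:2]
                kwargs = {
                    "normal_depth": int(depths[1]),
                    "normal_alt_reads": int(ad[1, alt_i + 1]) if ad.shape[1] > alt_i + 1 else 0,
                    "normal_gq": float(gq[1]),
                    "normal_nonref_gt": any(a not in (0, -1) for a in n_gt),
                }
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=str(alt),
                    tumour_depth=t_dp,
                    tumour_vaf=vaf,
                    site_qual=float(v.QUAL) if v.QUAL is not None else 0.0,
                    mq=float(mq) if mq is not None else 0.0,
                    tumour_gq=float(gq[0]),
                    dbsnp=bool(v.INFO.get("DB")),
                    gene=gene,
                    annotation_class=ann_class,
                    **kwargs,
                )
            )
    return records


def write_filtered_vcf(records: Sequence[VariantRecord], verdicts, path: str | Path) -> None:
    """Write records with PASS / semicolon-joined reasons in FILTER."""
    lines = [VCF_HEADER + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
    for r, v in zip(records, verdicts):
        filt = "PASS" if v.passed else ";".join(v.reasons)
        info = f"MQ={r.mq:g}" + (";DB" if r.dbsnp else "")
        lines.append("\t".join([r.chrom, str(r.pos), ".", r.ref, r.alt, f"{r.site_qual:g}", filt, info]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_positions(path: str | Path) -> list[tuple[str, int]]:
    """Read control-called variant positions from a 2-column TSV (chrom, pos)."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}: line {i}: expected chrom<TAB>pos")
        out.append((parts[0], int(parts[1])))
    return out


def write_positions(positions: Sequence[tuple[str, int]], path: str | Path) -> None:
    Path(path).write_text("".join(f"{c}\t{p}\n" for c, p in positions))


# ---------------------------------------------------------------------------
# plates, gene lists, tables, manifests

def read_plate(path: str | Path) -> pd.DataFrame:
    from .doseresponse import validate_plate

    return validate_plate(pd.read_csv(path))


def write_plate(plate: pd.DataFrame, path: str | Path) -> None:
    plate.to_csv(path, index=False)


def read_gene_list(path: str | Path) -> list[str]:
    return [l.strip() for l in Path(path).read_text().splitlines() if l.strip() and not l.startswith("#")]


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def write_manifest(path: str | Path, *, command: str, inputs: dict, config_digest: str, seed: int | None = None) -> None:
    """JSON run manifest: inputs, config hash, package version, seed.

    Deliberately timestamp-free so identical runs are byte-identical.
    """
    manifest = {
        "tool": "nephrokit",
        "version": __version__,
        "command": command,
        "inputs": inputs,
        "config_sha256": config_digest,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
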