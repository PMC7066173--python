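"""Run configuration: every analysis threshold as a named, overridable value.

Defaults are the values used throughout the study this toolkit reproduces the
procedures of: cosine target 0.9 with minimum gain 0.01 and forced clock-like
signatures SBS1/SBS5 for refitting; 40% mitochondrial fraction and 1000
transcripts for cell QC; the 5-cells / 2-cells-with-2-transcripts gene
filter; 10,000-transcript log normalization; 1.8-fold and 5% Bonferroni for
marker detection; the somatic hard-filter thresholds (10x/20x coverage, VAF
0.1, site quality 100/250, MQ 60 for indels, 100 bp indel proximity,
GQ 10/99 for signature-grade calls); six concentrations and four technical
replicates for drug screens.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

DRIVER_CLASSES: tuple[str, ...] = (
    "missense",
    "start_lost",
    "stop_gained",
    "inframe_insertion",
    "inframe_deletion",
    "frameshift",
)


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass
class SignatureConfig:
    """Greedy signature-refit parameters."""

    cos_target: float = 0.9
    min_gain: float = 0.01
    forced_ids: list[str] = field(default_factory=lambda: ["SBS1", "SBS5"])
    #: Reference signatures dropped when loading the set (e.g. SBS40, which is
    #: close to SBS5 and indistinguishable from it in small cohorts).
    excluded_ids: list[str] = field(default_factory=lambda: ["SBS40"])

    def validate(self) -> None:
        _check(0.0 <= self.cos_target <= 1.0, "signature.cos_target must be in [0,1]")
        _check(0.0 <= self.min_gain <= 1.0, "signature.min_gain must be in [0,1]")
        _check(len(self.forced_ids) >= 1, "signature.forced_ids must be non-empty")


@dataclass
class ScConfig:
    """Single-cell QC and normalization parameters."""

    max_mito_frac: float = 0.40
    min_transcripts: int = 1000
    gene_min_cells: int = 5
    gene_min_cells_ge2: int = 2
    norm_scale: int = 10000
    n_bins: int = 24
    n_ctrl: int = 100
    quantile_method: str = "linear"  # numpy type-7 interpolation

    def validate(self) -> None:
        _check(0.0 <= self.max_mito_frac <= 1.0, "sc.max_mito_frac must be in [0,1]")
        for name in ("min_transcripts", "gene_min_cells", "gene_min_cells_ge2", "norm_scale", "n_bins", "n_ctrl"):
            _check(getattr(self, name) >= 0, f"sc.{name} must be >= 0")


@dataclass
class DeConfig:
    """Marker-detection parameters."""

    fold_cutoff: float = 1.8
    alpha: float = 0.05

    def validate(self) -> None:
        _check(self.fold_cutoff > 1.0, "de.fold_cutoff must be > 1")
        _check(0.0 <= self.alpha <= 1.0, "de.alpha must be in [0,1]")


@dataclass
class VariantConfig:
    """Somatic hard-filter thresholds (all comparisons inclusive)."""

    min_depth: int = 10
    min_depth_no_normal: int = 20
    min_vaf: float = 0.1
    min_qual_snv: float = 100.0
    min_qual_indel: float = 250.0
    min_mq_indel: float = 60.0
    indel_proximity_bp: int = 100
    #: alt-supporting reads in the normal at or above this count are
    #: "evidence in the normal" and fail the variant
    normal_evidence_min_reads: int = 1
    signature_normal_gq: float = 10.0
    signature_tumour_gq: float = 99.0
    driver_classes: list[str] = field(default_factory=lambda: list(DRIVER_CLASSES))

    def validate(self) -> None:
        _check(0.0 <= self.min_vaf <= 1.0, "variant.min_vaf must be in [0,1]")
        for name in ("min_depth", "min_depth_no_normal", "indel_proximity_bp", "normal_evidence_min_reads"):
            _check(getattr(self, name) >= 0, f"variant.{name} must be >= 0")
        for name in ("min_qual_snv", "min_qual_indel", "min_mq_indel", "signature_normal_gq", "signature_tumour_gq"):
            _check(getattr(self, name) >= 0, f"variant.{name} must be >= 0")


@dataclass
class DrcConfig:
    """Drug-screen layout and fitting parameters."""

    n_concentrations: int = 6
    replicates: int = 4
    equal_variance_ttest: bool = True

    def validate(self) -> None:
        _check(self.n_concentrations >= 4, "drc.n_concentrations must be >= 4")
        _check(self.replicates >= 1, "drc.replicates must be >= 1")


@dataclass
class RunConfig:
    """Bundle of all stage configurations, YAML-serializable."""

    signature: SignatureConfig = field(default_factory=SignatureConfig)
    sc: ScConfig = field(default_factory=ScConfig)
    de: DeConfig = field(default_factory=DeConfig)
    variant: VariantConfig = field(default_factory=VariantConfig)
    drc: DrcConfig = field(default_factory=DrcConfig)

    def validate(self) -> "RunConfig":
        for section in (self.signature, self.sc, self.de, self.variant, self.drc):
            section.validate()
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sections = {
            "signature": SignatureConfig,
            "sc": ScConfig,
            "de": DeConfig,
            "variant": VariantConfig,
            "drc": DrcConfig,
        }
        kwargs = {}
        for key, typ in sections.items():
            sub = d.get(key, {})
            known = {f.name for f in dataclasses.fields(typ)}
            unknown = set(sub) - known
            if unknown:
                raise ConfigurationError(f"unknown {key} config keys: {sorted(unknown)}")
            kwargs[key] = typ(**sub)
        unknown = set(d) - set(sections)
        if unknown:
            raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
        return cls(**kwargs).validate()

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    def digest(self) -> str:
        """Stable sha256 of the canonical YAML serialization."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()
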