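"""Greedy forward-selection mutational-signature refitting.

A tumour's 96-channel substitution catalog is modeled as a non-negative
mixture of reference signatures (96-dimensional probability columns). The
clock-like signatures SBS1 and SBS5 accumulate with age and are assumed
present in every sample, so the catalog is first refit to the forced set
alone by non-negative least squares. If the cosine similarity between the
reconstruction and the catalog already reaches the target (0.9) selection
stops. Otherwise each remaining candidate is tried jointly with the current
selection, the candidate giving the largest cosine increase is added, and the
loop repeats until the target is reached or the best achievable gain drops
below the minimum (0.01), in which case the offending candidate is *not*
added.

Exposures are reported on the mutation-count scale (the absolute
contribution of each signature) along with their normalized fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .channels import CHANNELS
from .config import RunConfig, SignatureConfig
from .errors import ConfigurationError, ValidationError

#: absolute tolerance for treating two candidate cosines as tied
TIE_TOL = 1e-12


@dataclass
class MutationalProfile:
    """A per-sample 96-channel substitution catalog in canonical order."""

    sample_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValidationError(
                f"profile {self.sample_id!r}: expected 96 channels, got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            bad = int(np.argmin(self.counts))
            raise ValidationError(
                f"profile {self.sample_id!r}: negative count in channel {CHANNELS[bad]}"
            )

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class SignatureSet:
    """Reference signatures: a 96 x K column-stochastic matrix with names."""

    names: list[str]
    matrix: np.ndarray
    forced: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.names)):
            raise ValidationError(
                f"signature matrix shape {self.matrix.shape} does not match {len(self.names)} names"
            )
        if len(set(self.names)) != len(self.names):
            raise ValidationError("duplicate signature names")
        if np.any(self.matrix < 0):
            raise ValidationError("signature matrix has negative entries")
        sums = self.matrix.sum(axis=0)
        off = np.abs(sums - 1.0) > 1e-9
        if np.any(off):
            raise ValidationError(
                f"signature column(s) not normalized: {[self.names[i] for i in np.flatnonzero(off)]}"
            )
        missing = [n for n in self.forced if n not in self.names]
        if missing:
            raise ConfigurationError(f"forced signature(s) missing from set: {missing}")

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ConfigurationError(f"signature {name!r} not in set") from None

    def columns(self, names: list[str]) -> np.ndarray:
        return self.matrix[:, [self.index(n) for n in names]]

    def subset(self, names: list[str]) -> "SignatureSet":
        return SignatureSet(list(names), self.columns(list(names)), [n for n in self.forced if n in names])

    def with_forced(self, forced: list[str]) -> "SignatureSet":
        return SignatureSet(self.names, self.matrix, list(forced))

    def exclude(self, names: list[str]) -> "SignatureSet":
        keep = [n for n in self.names if n not in set(names)]
        return SignatureSet(keep, self.columns(keep), [n for n in self.forced if n in keep])


@dataclass
class RefitResult:
    """Outcome of greedy selection for one sample."""

    sample_id: str
    selected: list[str]
    exposures: np.ndarray  # mutation-count scale, one per selected signature
    cosine_trace: list[float]  # after the forced refit and after each addition
    stop_reason: str  # target_reached | gain_below_threshold | candidates_exhausted

    @property
    def final_cosine(self) -> float:
        return self.cosine_trace[-1]

    @property
    def relative_contributions(self) -> np.ndarray:
        total = self.exposures.sum()
        if total == 0:
            return np.zeros_like(self.exposures)
        return self.exposures / total


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two non-negative 96-vectors (scale-invariant)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValidationError("cosine similarity requires non-negative vectors")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValidationError("cosine similarity undefined for an all-zero vector")
    return float(a @ b / (na * nb))


def refit_exposures(profile: MutationalProfile, signatures: SignatureSet) -> np.ndarray:
    """Non-negative least-squares exposures of *profile* on the full set.

    Minimizes ``||counts - matrix @ e||_2`` over ``e >= 0``; deterministic.
    """
    if not signatures.names:
        raise ValidationError("cannot refit against an empty signature set")
    e, _ = scipy.optimize.nnls(signatures.matrix, profile.counts)
    return e


def reconstruct(signatures: SignatureSet, exposures: np.ndarray) -> np.ndarray:
    """Reconstructed catalog ``matrix @ e``."""
    exposures = np.asarray(exposures, dtype=float)
    if exposures.shape != (len(signatures.names),):
        raise ValidationError("exposure vector length does not match signature count")
    return signatures.matrix @ exposures


def _refit_cosine(profile: MutationalProfile, signatures: SignatureSet, names: list[str]) -> tuple[np.ndarray, float]:
    sub = signatures.subset(names)
    e = refit_exposures(profile, sub)
    rec = reconstruct(sub, e)
    if not rec.any():  # NNLS drove everything to zero: no overlap with profile
        return e, 0.0
    return e, cosine_similarity(profile.counts, rec)


def greedy_select(
    profile: MutationalProfile,
    signatures: SignatureSet,
    cos_target: float = 0.9,
    min_gain: float = 0.01,
) -> RefitResult:
    """Greedy forward selection with forced clock signatures.

    The forced signatures are refit first and the target check (``cosine >=
    cos_target``) is applied after every refit including that initial one. In
    each round every unselected candidate is refit jointly with the current
    selection; the best candidate (ties broken by reference-set order) is
    added only if its cosine gain is at least *min_gain* — a round whose best
    gain falls below the threshold stops selection without adding.
    """
    if profile.total == 0 or not profile.counts.any():
        raise ValidationError(f"profile {profile.sample_id!r} is all zero; nothing to fit")
    forced = [n for n in signatures.forced]
    if not forced:
        raise ConfigurationError("signature set declares no forced signatures")

    selected = list(forced)
    exposures, cos = _refit_cosine(profile, signatures, selected)
    trace = [cos]
    stop = "candidates_exhausted"
    while True:
        if cos >= cos_target:
            stop = "target_reached"
            break
        candidates = [n for n in signatures.names if n not in selected]
        if not candidates:
            stop = "candidates_exhausted"
            break
        cand_cos = np.array([_refit_cosine(profile, signatures, selected + [c])[1] for c in candidates])
        best_idx = int(np.flatnonzero(cand_cos >= cand_cos.max() - TIE_TOL)[0])
        gain = cand_cos[best_idx] - cos
        if gain < min_gain:
            stop = "gain_below_threshold"
            break
        selected.append(candidates[best_idx])
        exposures, cos = _refit_cosine(profile, signatures, selected)
        trace.append(cos)
    return RefitResult(profile.sample_id, selected, exposures, trace, stop)


def refit_cohort(
    profiles: dict[str, MutationalProfile],
    signatures: SignatureSet,
    config: RunConfig | SignatureConfig | None = None,
) -> pd.DataFrame:
    """Run greedy selection over a cohort.

    Returns one row per sample with columns: ``sample``, ``total_mutations``,
    ``selected`` (comma-joined, in selection order), ``final_cosine``,
    ``stop_reason``, plus one absolute-exposure column per reference
    signature (zero when unselected). Zero-mutation samples are flagged with
    ``stop_reason = "empty_profile"`` and no selection is attempted.
    """
    if not profiles:
        raise ValidationError("cohort is empty")
    sig_cfg = config.signature if isinstance(config, RunConfig) else (config or SignatureConfig())
    sigset = signatures
    if sig_cfg.excluded_ids:
        sigset = sigset.exclude([n for n in sig_cfg.excluded_ids if n in sigset.names])
    sigset = sigset.with_forced(sig_cfg.forced_ids)

    rows = []
    for sample, profile in profiles.items():
        base = {"sample": sample, "total_mutations": profile.total}
        expo = dict.fromkeys(sigset.names, 0.0)
        if profile.total == 0:
            rows.append({**base, "selected": "", "final_cosine": np.nan, "stop_reason": "empty_profile", **expo})
            continue
        try:
            res = greedy_select(profile, sigset, sig_cfg.cos_target, sig_cfg.min_gain)
        except ValidationError as exc:
            raise ValidationError(f"sample {sample!r}: {exc}") from exc
        for name, e in zip(res.selected, res.exposures):
            expo[name] = float(e)
        rows.append(
            {
                **base,
                "selected": ",".join(res.selected),
                "final_cosine": res.final_cosine,
                "stop_reason": res.stop_reason,
                **expo,
            }
        )
    return pd.DataFrame(rows)


def selection_trace(
    profiles: dict[str, MutationalProfile],
    signatures: SignatureSet,
    config: RunConfig | SignatureConfig | None = None,
) -> pd.DataFrame:
    """Per-sample selection traces: (sample, step, signature, cosine)."""
    sig_cfg = config.signature if isinstance(config, RunConfig) else (config or SignatureConfig())
    sigset = signatures
    if sig_cfg.excluded_ids:
        sigset = sigset.exclude([n for n in sig_cfg.excluded_ids if n in sigset.names])
    sigset = sigset.with_forced(sig_cfg.forced_ids)
    rows = []
    for sample, profile in profiles.items():
        if profile.total == 0:
            continue
        res = greedy_select(profile, sigset, sig_cfg.cos_target, sig_cfg.min_gain)
        n_forced = len(sigset.forced)
        rows.append({"sample": sample, "step": 0, "signature": "+".join(res.selected[:n_forced]), "cosine": res.cosine_trace[0]})
        for step, (name, cos) in enumerate(zip(res.selected[n_forced:], res.cosine_trace[1:]), start=1):
            rows.append({"sample": sample, "step": step, "signature": name, "cosine": cos})
    return pd.DataFrame(rows, columns=["sample", "step", "signature", "cosine"])
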