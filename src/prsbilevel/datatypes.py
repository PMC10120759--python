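"""Core in-memory containers shared across the package.

Summary statistics and annotation maps are thin, validated wrappers around
pandas/numpy objects; LD is carried as a list of block-diagonal correlation
matrices (cross-block LD is assumed zero, i.e. the reference panel is used
only for local patterns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel annotation label for variants without any annotation.
NO_ANNOTATION = "__none__"

SUMSTAT_COLUMNS = ["variant_id", "chrom", "pos", "a1", "a2", "beta_hat"]


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class SummaryStats:
    """Per-variant marginal GWAS effects on the standardized scale.

    Parameters
    ----------
    table
        DataFrame with columns ``variant_id, chrom, pos, a1, a2, beta_hat``.
        ``beta_hat`` is the marginal effect of one standardized-allele unit on
        the standardized phenotype (``G^T y / N``).
    n_gwas
        GWAS sample size N (a single value for all variants).
    """

    table: pd.DataFrame
    n_gwas: int

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTAT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"summary statistics missing columns: {missing}")
        if self.n_gwas < 1:
            raise ValidationError(f"n_gwas must be >= 1, got {self.n_gwas}")
        ids = self.table["variant_id"]
        if ids.duplicated().any():
            first = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate variant_id: {first!r}")
        beta = self.table["beta_hat"].to_numpy(float)
        if not np.all(np.isfinite(beta)):
            raise ValidationError("beta_hat contains non-finite values")
        same = self.table["a1"].astype(str) == self.table["a2"].astype(str)
        if same.any():
            raise ValidationError(
                f"a1 == a2 for variant {self.table.loc[same, 'variant_id'].iloc[0]!r}"
            )
        self.table = self.table.reset_index(drop=True)

    @property
    def variant_ids(self) -> list[str]:
        return self.table["variant_id"].tolist()

    @property
    def beta_hat(self) -> np.ndarray:
        return self.table["beta_hat"].to_numpy(float)

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, variant_ids: list[str]) -> "SummaryStats":
        """Restrict (and reorder) to the given variant ids."""
        idx = self.table.set_index("variant_id")
        missing = [v for v in variant_ids if v not in idx.index]
        if missing:
            raise ValidationError(f"variants absent from summary stats: {missing[:5]}")
        sub = idx.loc[variant_ids].reset_index()
        return SummaryStats(sub[SUMSTAT_COLUMNS], self.n_gwas)


@dataclass
class LDBlock:
    """One LD block: ordered variant ids and their correlation matrix D."""

    variant_ids: list[str]
    D: np.ndarray

    #: tolerances for the symmetry / PSD invariants
    SYM_TOL = 1e-10
    PSD_TOL = 1e-8

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        m = len(self.variant_ids)
        if self.D.shape != (m, m):
            raise ValidationError(f"D shape {self.D.shape} != ({m}, {m})")

    def validate(self) -> None:
        if not np.allclose(self.D, self.D.T, atol=self.SYM_TOL, rtol=0.0):
            raise ValidationError("LD matrix not symmetric")
        if not np.allclose(np.diag(self.D), 1.0, atol=1e-8):
            raise ValidationError("LD matrix diagonal != 1")
        if np.abs(self.D).max() > 1.0 + 1e-8:
            raise ValidationError("LD entries outside [-1, 1]")
        if len(self.variant_ids) > 0:
            w = np.linalg.eigvalsh(self.D)
            if w.min() < -self.PSD_TOL:
                raise ValidationError(
                    f"LD matrix not PSD (min eigenvalue {w.min():.3e}); "
                    "consider the ridge-repair flag"
                )

    def __len__(self) -> int:
        return len(self.variant_ids)


@dataclass
class AnnotationMap:
    """Variant -> set-of-group-labels mapping (possibly overlapping).

    ``groups`` fixes the group order K; ``assignment`` maps each variant id to
    a non-empty tuple of labels. Variants without annotation carry the
    sentinel label ``"__none__"``.
    """

    groups: list[str]
    assignment: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        known = set(self.groups)
        for vid, labels in self.assignment.items():
            if not labels:
                raise ValidationError(f"variant {vid!r} has no group labels")
            unknown = [g for g in labels if g not in known]
            if unknown:
                raise ValidationError(
                    f"variant {vid!r} assigned to unknown groups {unknown}"
                )

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def labels_for(self, variant_id: str) -> tuple[str, ...]:
        """Group labels of a variant; unseen variants get the sentinel."""
        return self.assignment.get(variant_id, (NO_ANNOTATION,))

    def members(self, group: str) -> set[str]:
        if group not in self.groups:
            raise ValidationError(f"unknown group {group!r}")
        return {v for v, labs in self.assignment.items() if group in labs}


@dataclass
class ExpandedDesign:
    """Per-(variant, group) copy layout for the bilevel prior.

    Each variant contributes one copy per annotation group it belongs to;
    shrinkage parameters and posterior effects live on copies, and the
    per-variant total effect is the sum over its copies.
    """

    variant_ids: list[str]
    groups: list[str]
    copy_variant: np.ndarray  # (m_prime,) variant index of each copy
    copy_group: np.ndarray  # (m_prime,) group index of each copy

    def __post_init__(self) -> None:
        self.copy_variant = np.asarray(self.copy_variant, dtype=np.int64)
        self.copy_group = np.asarray(self.copy_group, dtype=np.int64)
        if self.copy_variant.shape != self.copy_group.shape:
            raise ValidationError("copy index arrays differ in length")
        counts = np.bincount(self.copy_variant, minlength=len(self.variant_ids))
        if counts.min(initial=1) < 1 or len(counts) != len(self.variant_ids):
            raise ValidationError("every variant must have at least one copy")

    @property
    def m_prime(self) -> int:
        return len(self.copy_variant)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def group_sizes(self) -> np.ndarray:
        """M_k counted on copies, ordered as ``groups``."""
        return np.bincount(self.copy_group, minlength=len(self.groups))

    def copies_of_variant(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.copy_variant == j)

    def collapse_to_variants(self, values: np.ndarray) -> np.ndarray:
        """Sum a per-copy vector over copies of each variant."""
        values = np.asarray(values, dtype=float)
        out = np.zeros(self.n_variants)
        np.add.at(out, self.copy_variant, values)
        return out


@dataclass
class PosteriorSummary:
    """Posterior-mean effects and chain diagnostics from the Gibbs sampler."""

    design: ExpandedDesign
    beta_tilde_copies: np.ndarray  # (m_prime,)
    beta_tilde_variant: np.ndarray  # (n_variants,)
    delta2_mean: np.ndarray  # (K,)
    sigma2_mean: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = self.design.collapse_to_variants(self.beta_tilde_copies)
        if not np.allclose(expected, self.beta_tilde_variant, atol=1e-10):
            raise ValidationError(
                "beta_tilde_variant is not the per-variant sum of copies"
            )
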