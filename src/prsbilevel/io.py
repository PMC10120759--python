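"""Readers/writers for summary statistics, annotations, genotypes and LD.

Summary statistics and annotation files are plain TSV; genotypes use the
PLINK .bed/.bim/.fam triplet (a minimal 2-bit codec implemented here);
precomputed LD blocks can be stored in an HDF5 container. Odds ratios are
log-transformed at read time so the samplers only ever see additive effects.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    NO_ANNOTATION,
    SUMSTAT_COLUMNS,
    AnnotationMap,
    LDBlock,
    SummaryStats,
    ValidationError,
)

logger = logging.getLogger(__name__)

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class FormatError(ValueError):
    """Raised when an input file does not match its declared format."""


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def read_sumstats(
    path: str | os.PathLike,
    dialect: str = "prscs",
    n_gwas: int | None = None,
    column_map: dict[str, str] | None = None,
) -> SummaryStats:
    """Read GWAS summary statistics from a whitespace/tab-delimited file.

    Parameters
    ----------
    dialect
        ``"prscs"`` expects columns SNP, A1, A2 and BETA or OR (CHR/BP/N
        optional); ``"generic"`` uses ``column_map`` mapping the canonical
        names (variant_id, chrom, pos, a1, a2, beta or or_, se, n) to the
        file's column headers.
    n_gwas
        GWAS sample size; required when the file has no N column. A
        per-variant N column is accepted and its median used, with a warning.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if df.empty:
        raise ValidationError(f"empty summary statistics file: {path}")

    if dialect == "prscs":
        colmap = {"variant_id": "SNP", "a1": "A1", "a2": "A2",
                  "beta": "BETA", "or_": "OR", "chrom": "CHR", "pos": "BP",
                  "se": "SE", "n": "N"}
    elif dialect == "generic":
        if not column_map:
            raise ValidationError("generic dialect requires a column_map")
        colmap = dict(column_map)
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")

    def col(name: str) -> pd.Series | None:
        c = colmap.get(name)
        return df[c] if c is not None and c in df.columns else None

    for required in ("variant_id", "a1", "a2"):
        if col(required) is None:
            raise FormatError(f"missing required column for {required!r} "
                              f"(expected header {colmap.get(required)!r})")

    beta_col, or_col = col("beta"), col("or_")
    if beta_col is not None:
        effect = pd.to_numeric(beta_col, errors="coerce")
    elif or_col is not None:
        odds = pd.to_numeric(or_col, errors="coerce")
        with np.errstate(divide="ignore", invalid="ignore"):
            effect = np.log(odds)
    else:
        raise FormatError("missing effect column (BETA or OR)")

    keep = np.isfinite(effect.to_numpy(float))
    se_col = col("se")
    if se_col is not None:
        se = pd.to_numeric(se_col, errors="coerce").to_numpy(float)
        keep &= np.isfinite(se) & (se > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_sumstats: dropped %d rows with missing/zero-SE effects",
                    n_dropped)
    df, effect = df.loc[keep], effect[keep]

    n_col = col("n")
    if n_col is not None:
        n_values = pd.to_numeric(n_col[keep], errors="coerce").dropna()
        n_eff = int(n_values.median())
        if n_values.nunique() > 1:
            logger.warning("per-variant N column found; using median N=%d", n_eff)
        if n_gwas is None:
            n_gwas = n_eff
    if n_gwas is None:
        raise ValidationError("n_gwas must be given when the file has no N column")

    chrom = col("chrom")
    pos = col("pos")
    table = pd.DataFrame({
        "variant_id": df[colmap["variant_id"]].astype(str),
        "chrom": chrom.astype(str) if chrom is not None else "0",
        "pos": pd.to_numeric(pos, errors="coerce").fillna(0).astype(int)
        if pos is not None else 0,
        "a1": df[colmap["a1"]].astype(str).str.upper(),
        "a2": df[colmap["a2"]].astype(str).str.upper(),
        "beta_hat": effect.to_numpy(float),
    })
    return SummaryStats(table, int(n_gwas))


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_annotations(path: str | os.PathLike) -> AnnotationMap:
    """Read a variant->groups TSV (``variant_id<TAB>label1,label2``).

    Variants with an empty label field receive the ``"__none__"`` sentinel.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                         names=["variant_id", "labels"], keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty annotation file: {path}") from None
    if df.empty:
        raise ValidationError(f"empty annotation file: {path}")
    # tolerate a header row
    if df.iloc[0, 0].lower() in ("variant_id", "snp", "id"):
        df = df.iloc[1:]
    if df.empty:
        raise ValidationError(f"annotation file has no records: {path}")

    assignment: dict[str, tuple[str, ...]] = {}
    groups: list[str] = []
    seen: set[str] = set()
    for vid, labels in zip(df["variant_id"], df["labels"]):
        labs = tuple(dict.fromkeys(s.strip() for s in str(labels).split(",")
                                   if s.strip())) or (NO_ANNOTATION,)
        assignment[str(vid)] = labs
        for g in labs:
            if g not in seen:
                seen.add(g)
                groups.append(g)
    return AnnotationMap(groups=groups, assignment=assignment)


def write_annotations(path: str | os.PathLike, am: AnnotationMap) -> None:
    with open(path, "w") as fh:
        for vid, labels in am.assignment.items():
            fh.write(f"{vid}\t{','.join(labels)}\n")


# ---------------------------------------------------------------------------
# PLINK triplet codec
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b\x01"  # SNP-major
# 2-bit codes -> a1-allele dosage (01 = missing)
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix: str | os.PathLike):
    """Read a .bed/.bim/.fam triplet.

    Returns ``(genotypes, bim, fam)`` where genotypes is an (n_individuals,
    n_variants) float array of a1-allele dosages with NaN for missing.
    """
    prefix = str(prefix)
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=["chrom", "variant_id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "variant_id": str, "a1": str, "a2": str})
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype={"fid": str, "iid": str})
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix + ".bed", dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed is not a SNP-major PLINK bed file")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if len(body) != bytes_per_snp * m:
        raise FormatError(f"{prefix}.bed has unexpected length")
    codes = body.reshape(m, bytes_per_snp)
    # unpack 2-bit fields, sample-index fastest within a byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    unpacked = (codes[:, :, None] >> shifts[None, None, :]) & 0b11
    unpacked = unpacked.reshape(m, bytes_per_snp * 4)[:, :n]
    geno = _BED_DECODE[unpacked].T  # (n, m)
    return geno, bim, fam


def write_plink(prefix: str | os.PathLike, genotypes: np.ndarray,
                bim: pd.DataFrame, fam: pd.DataFrame) -> None:
    """Write a1-allele dosages (0/1/2, NaN missing) as a PLINK triplet."""
    prefix = str(prefix)
    geno = np.asarray(genotypes, dtype=float)
    n, m = geno.shape
    if len(fam) != n or len(bim) != m:
        raise ValidationError("genotype shape inconsistent with bim/fam")
    codes = np.full((m, n), 1, dtype=np.uint8)  # 01 = missing
    with np.errstate(invalid="ignore"):
        codes[(geno == 2).T] = 0b00
        codes[(geno == 1).T] = 0b10
        codes[(geno == 0).T] = 0b11
    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((m, pad), dtype=np.uint8)], axis=1)
    packed = (codes[:, 0::4] | (codes[:, 1::4] << 2)
              | (codes[:, 2::4] << 4) | (codes[:, 3::4] << 6))
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        packed.astype(np.uint8).tofile(fh)
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)


def standardize_genotypes(geno: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages, then center/scale each column."""
    geno = np.asarray(geno, dtype=float).copy()
    col_mean = np.nanmean(geno, axis=0)
    nan_rows, nan_cols = np.nonzero(np.isnan(geno))
    geno[nan_rows, nan_cols] = col_mean[nan_cols]
    geno -= geno.mean(axis=0)
    sd = geno.std(axis=0)
    sd[sd == 0] = 1.0
    return geno / sd


# ---------------------------------------------------------------------------
# LD reference
# ---------------------------------------------------------------------------

def read_ld_reference(
    path: str | os.PathLike,
    blocks: pd.DataFrame | None = None,
    ridge: bool = False,
    ridge_eps: float = 1e-6,
) -> list[LDBlock]:
    """Build LD blocks from a reference panel or a precomputed container.

    ``path`` is either a PLINK prefix (then ``blocks`` must give half-open
    1-based intervals with columns chrom, start, end) or an HDF5 file written
    by :func:`write_ld_h5`. D is the sample correlation of standardized
    reference dosages; monomorphic variants are dropped with a logged count.
    """
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        return _read_ld_h5(path)
    if blocks is None:
        raise ValidationError("block boundary table required for a PLINK panel")
    geno, bim, _fam = read_plink(path)
    out: list[LDBlock] = []
    n_mono = 0
    for _, row in blocks.iterrows():
        in_block = ((bim["chrom"].astype(str) == str(row["chrom"]))
                    & (bim["pos"] >= int(row["start"]))
                    & (bim["pos"] < int(row["end"])))
        idx = np.flatnonzero(in_block.to_numpy())
        if idx.size == 0:
            logger.warning("LD block %s:[%s,%s) contains no panel variants; skipped",
                           row["chrom"], row["start"], row["end"])
            continue
        sub = geno[:, idx]
        sd = np.nanstd(sub, axis=0)
        poly = sd > 0
        n_mono += int((~poly).sum())
        idx = idx[poly]
        if idx.size == 0:
            continue
        D = np.corrcoef(standardize_genotypes(geno[:, idx]), rowvar=False)
        D = np.atleast_2d(D)
        block = LDBlock(bim["variant_id"].iloc[idx].tolist(), D)
        out.append(_check_or_repair(block, ridge, ridge_eps))
    if n_mono:
        logger.info("read_ld_reference: dropped %d monomorphic variants", n_mono)
    return out


def _check_or_repair(block: LDBlock, ridge: bool, eps: float) -> LDBlock:
    try:
        block.validate()
    except ValidationError:
        if not ridge:
            raise
        m = len(block)
        D = (block.D + eps * np.eye(m)) / (1.0 + eps)
        block = LDBlock(block.variant_ids, D)
        block.validate()
    return block


def write_ld_h5(path: str | os.PathLike, blocks: list[LDBlock]) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        for i, block in enumerate(blocks):
            grp = fh.create_group(f"block{i:05d}")
            grp.create_dataset(
                "variant_ids",
                data=np.array(block.variant_ids, dtype="S"))
            grp.create_dataset("D", data=block.D)


def _read_ld_h5(path: str) -> list[LDBlock]:
    import h5py

    out = []
    with h5py.File(path, "r") as fh:
        for key in sorted(fh.keys()):
            ids = [v.decode() for v in fh[key]["variant_ids"][()]]
            out.append(LDBlock(ids, fh[key]["D"][()]))
    for b in out:
        b.validate()
    return out


def block_variant_ids(blocks: list[LDBlock]) -> list[str]:
    ids: list[str] = []
    for b in blocks:
        ids.extend(b.variant_ids)
    return ids


def restrict_blocks(blocks: list[LDBlock], variant_ids: set[str]) -> list[LDBlock]:
    """Subset each block to the given variants, keeping block order."""
    out = []
    for b in blocks:
        keep = [i for i, v in enumerate(b.variant_ids) if v in variant_ids]
        if not keep:
            continue
        out.append(LDBlock([b.variant_ids[i] for i in keep],
                           b.D[np.ix_(keep, keep)]))
    return out


# ---------------------------------------------------------------------------
# allele alignment
# ---------------------------------------------------------------------------

def align_alleles(
    ss: SummaryStats,
    blocks: list[LDBlock],
    panel_alleles: pd.DataFrame,
    drop_ambiguous: bool = False,
) -> SummaryStats:
    """Harmonize summary-statistic alleles with the LD panel.

    Variants whose (a1, a2) are swapped relative to the panel have their
    effect sign flipped (and alleles swapped); strand-ambiguous (A/T, C/G)
    variants are removed when ``drop_ambiguous`` is set; variants with
    incompatible alleles are dropped with a warning. The result contains the
    intersection only, ordered to match the concatenated blocks.
    """
    panel = panel_alleles.set_index("variant_id")
    table = ss.table.set_index("variant_id")
    ordered_ids = [v for v in block_variant_ids(blocks) if v in table.index]

    rows = []
    n_flip = n_drop = 0
    for vid in ordered_ids:
        if vid not in panel.index:
            continue
        rec = table.loc[vid]
        a1, a2 = str(rec["a1"]).upper(), str(rec["a2"]).upper()
        if drop_ambiguous and (a1, a2) in AMBIGUOUS_PAIRS:
            n_drop += 1
            continue
        p1, p2 = str(panel.loc[vid, "a1"]).upper(), str(panel.loc[vid, "a2"]).upper()
        beta = float(rec["beta_hat"])
        if (a1, a2) == (p1, p2):
            pass
        elif (a1, a2) == (p2, p1):
            beta, a1, a2 = -beta, p1, p2
            n_flip += 1
        else:
            logger.warning("align_alleles: allele mismatch for %s; dropped", vid)
            continue
        rows.append({"variant_id": vid, "chrom": rec["chrom"], "pos": rec["pos"],
                     "a1": a1, "a2": a2, "beta_hat": beta})
    if not rows:
        raise ValidationError("no variants shared between summary stats and panel")
    if n_flip or n_drop:
        logger.info("align_alleles: flipped %d, dropped %d ambiguous",
                    n_flip, n_drop)
    return SummaryStats(pd.DataFrame(rows, columns=SUMSTAT_COLUMNS), ss.n_gwas)


# ---------------------------------------------------------------------------
# posterior effect tables
# ---------------------------------------------------------------------------

def write_posterior(prefix: str | os.PathLike, post, ss: SummaryStats) -> None:
    """Write per-copy and aggregated per-variant posterior effect tables.

    ``<prefix>.copies.tsv`` has one row per (variant, group) copy with
    columns ``variant_id chrom pos a1 beta_tilde group``;
    ``<prefix>.variants.tsv`` aggregates copies per variant.
    """
    prefix = str(prefix)
    d = post.design
    meta = ss.table.set_index("variant_id")
    vids = [d.variant_ids[j] for j in d.copy_variant]
    copies = pd.DataFrame({
        "variant_id": vids,
        "chrom": meta.loc[vids, "chrom"].to_numpy(),
        "pos": meta.loc[vids, "pos"].to_numpy(),
        "a1": meta.loc[vids, "a1"].to_numpy(),
        "beta_tilde": post.beta_tilde_copies,
        "group": [d.groups[k] for k in d.copy_group],
    })
    copies.to_csv(prefix + ".copies.tsv", sep="\t", index=False,
                  float_format="%.17g")
    per_variant = pd.DataFrame({
        "variant_id": d.variant_ids,
        "chrom": meta.loc[d.variant_ids, "chrom"].to_numpy(),
        "pos": meta.loc[d.variant_ids, "pos"].to_numpy(),
        "a1": meta.loc[d.variant_ids, "a1"].to_numpy(),
        "beta_tilde": post.beta_tilde_variant,
    })
    per_variant.to_csv(prefix + ".variants.tsv", sep="\t", index=False,
                       float_format="%.17g")


def read_effects(path: str | os.PathLike) -> pd.DataFrame:
    """Read an effect table written by :func:`write_posterior`."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str})
    if "beta_tilde" not in df.columns or "variant_id" not in df.columns:
        raise FormatError(f"not an effect table: {path}")
    return df


def read_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    """Read a phenotype TSV with columns iid, phenotype."""
    df = pd.read_csv(path, sep="\t", dtype={"iid": str})
    if "iid" not in df.columns or "phenotype" not in df.columns:
        raise FormatError(f"phenotype file needs 'iid' and 'phenotype': {path}")
    return df
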