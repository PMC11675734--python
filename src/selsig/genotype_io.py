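"""PLINK-format genotype input/output and quality control.

The central container is :class:`GenotypeDataset`: an animals x SNPs matrix of
allele dosages (count of the A1 allele, 0/1/2, with -1 marking a missing
genotype) together with a marker map (chromosome, bp position, alleles) and
per-animal breed and group labels.  Breeds nest within groups: every breed
code maps to exactly one group label.

Readers/writers cover PLINK 1 text (``.ped``/``.map``) and binary
(``.bed``/``.bim``/``.fam``, SNP-major v1.00) formats.  Coordinates are
1-based inclusive throughout, following the PLINK map convention.

Quality control applies the classical panel filters in a fixed, documented
order: unmapped markers, animal call rate, SNP call rate, minor allele
frequency, and a Hardy-Weinberg exact test on the pooled sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = np.int8(-1)
"""Sentinel dosage code for a missing genotype."""

_ANIMAL_COLS = ["animal_id", "breed", "group"]
_SNP_COLS = ["snp_id", "chrom", "pos", "a1", "a2"]


def _ext(prefix: str | Path, suffix: str) -> Path:
    """Append an extension to a path prefix (dot-safe, unlike with_suffix)."""
    return Path(str(prefix) + suffix)


class FormatError(ValueError):
    """Raised when PLINK files are malformed or mutually inconsistent."""


class QCError(ValueError):
    """Raised when quality control empties the dataset."""


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------

@dataclass
class GenotypeDataset:
    """Diploid biallelic genotypes plus marker map and animal labels.

    Parameters
    ----------
    genotypes:
        ``int8`` array of shape ``(n_animals, n_snps)`` with values in
        ``{0, 1, 2, MISSING}`` counting copies of the A1 allele.
    animals:
        DataFrame with columns ``animal_id``, ``breed``, ``group``.
    snps:
        DataFrame with columns ``snp_id``, ``chrom`` (positive int),
        ``pos`` (1-based bp), ``a1``, ``a2``; sorted by (chrom, pos).
    """

    genotypes: np.ndarray
    animals: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.animals = self.animals.reset_index(drop=True)
        self.snps = self.snps.reset_index(drop=True)
        if self.genotypes.ndim != 2:
            raise FormatError("genotype matrix must be 2-D")
        n, m = self.genotypes.shape
        if n != len(self.animals) or m != len(self.snps):
            raise FormatError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.animals)} animals x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise FormatError("genotype codes must be 0/1/2 or missing (-1)")
        if self.animals["animal_id"].duplicated().any():
            raise FormatError("duplicate animal_id")
        if self.snps["snp_id"].duplicated().any():
            raise FormatError("duplicate snp_id")
        # every breed belongs to exactly one group
        bg = self.animals.groupby("breed")["group"].nunique()
        if (bg > 1).any():
            raise FormatError("a breed maps to more than one group")
        # map sorted by (chrom, pos)
        order = np.lexsort((self.snps["pos"].to_numpy(),
                            self.snps["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(m)):
            self.snps = self.snps.iloc[order].reset_index(drop=True)
            self.genotypes = self.genotypes[:, order]

    # -- basic properties ---------------------------------------------------

    @property
    def n_animals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def allele_freq(self) -> np.ndarray:
        """Frequency of the A1 allele per SNP, from non-missing genotypes.

        Returns NaN for SNPs with no called genotypes.
        """
        g = self.genotypes.astype(np.float64)
        g[self.genotypes == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(g, axis=0) / 2.0

    def subset(self, animal_idx=None, snp_idx=None) -> "GenotypeDataset":
        """Row/column subset by positional index arrays (order preserved)."""
        ai = np.arange(self.n_animals) if animal_idx is None else np.asarray(animal_idx)
        si = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeDataset(
            genotypes=self.genotypes[np.ix_(ai, si)].copy(),
            animals=self.animals.iloc[ai],
            snps=self.snps.iloc[si],
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and self.animals[_ANIMAL_COLS].equals(other.animals[_ANIMAL_COLS])
            and self.snps[_SNP_COLS].astype(object).equals(
                other.snps[_SNP_COLS].astype(object))
        )

    def with_groups(self, breed_to_group: dict[str, str]) -> "GenotypeDataset":
        animals = self.animals.copy()
        animals["group"] = animals["breed"].map(breed_to_group).fillna("")
        return GenotypeDataset(self.genotypes, animals, self.snps)


# ---------------------------------------------------------------------------
# PLINK text (.ped/.map)
# ---------------------------------------------------------------------------

def _read_map(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise FormatError(f"{path}: map line needs 4 fields: {line!r}")
            rows.append((parts[0], parts[1], parts[3]))
    df = pd.DataFrame(rows, columns=["chrom", "snp_id", "pos"])
    try:
        df["chrom"] = df["chrom"].astype(int)
        df["pos"] = df["pos"].astype(int)
    except ValueError as exc:  # non-numeric chromosome names unsupported
        raise FormatError(f"{path}: non-integer chromosome or position") from exc
    return df


def _read_text(prefix: Path) -> GenotypeDataset:
    map_df = _read_map(_ext(prefix, ".map"))
    m = len(map_df)
    animals: list[tuple[str, str]] = []
    allele_rows: list[np.ndarray] = []
    with open(_ext(prefix, ".ped")) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{prefix}.ped line {ln}: expected {6 + 2 * m} fields, "
                    f"got {len(parts)}"
                )
            animals.append((parts[0], parts[1]))
            allele_rows.append(np.array(parts[6:], dtype=object))
    n = len(animals)
    geno = np.full((n, m), MISSING, dtype=np.int8)
    a1 = np.array([""] * m, dtype=object)
    a2 = np.array([""] * m, dtype=object)
    alleles = (
        np.array(allele_rows, dtype=object).reshape(n, m, 2)
        if n else np.empty((0, m, 2), dtype=object)
    )
    for j in range(m):
        col = alleles[:, j, :]
        seen: list[str] = []
        for row in col:
            for al in row:
                if al != "0" and al not in seen:
                    seen.append(al)
        if len(seen) > 2:
            raise FormatError(
                f"SNP {map_df['snp_id'][j]}: more than two alleles {seen}")
        # A1 = first allele encountered in file order (stable under
        # read -> write -> read); pad with placeholder for unseen allele
        s1 = seen[0] if seen else "A"
        s2 = seen[1] if len(seen) > 1 else ("B" if s1 != "B" else "A")
        a1[j], a2[j] = s1, s2
        ok = (col != "0").all(axis=1)
        dose = (col == s1).sum(axis=1).astype(np.int8)
        geno[ok, j] = dose[ok]
        half = ok ^ (col != "0").any(axis=1)
        if half.any():
            raise FormatError(
                f"SNP {map_df['snp_id'][j]}: half-missing genotype")
    snps = map_df.assign(a1=a1, a2=a2)[["snp_id", "chrom", "pos", "a1", "a2"]]
    adf = pd.DataFrame(
        {"animal_id": [i for _, i in animals],
         "breed": [f for f, _ in animals],
         "group": ""}
    )
    return GenotypeDataset(geno, adf, snps)


def _write_text(ds: GenotypeDataset, prefix: Path) -> None:
    with open(_ext(prefix, ".map"), "w") as fh:
        for _, s in ds.snps.iterrows():
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos}\n")
    a1 = ds.snps["a1"].to_numpy()
    a2 = ds.snps["a2"].to_numpy()
    lut = np.empty((4, ds.n_snps), dtype=object)  # rows: missing,0,1,2
    lut[0] = "0 0"
    lut[1] = [f"{y} {y}" for y in a2]
    lut[2] = [f"{x} {y}" for x, y in zip(a1, a2)]
    lut[3] = [f"{x} {x}" for x in a1]
    with open(_ext(prefix, ".ped"), "w") as fh:
        for i, (_, a) in enumerate(ds.animals.iterrows()):
            codes = ds.genotypes[i].astype(np.int64) + 1  # -1..2 -> 0..3
            fields = [str(a.breed or a.animal_id), str(a.animal_id),
                      "0", "0", "0", "-9"]
            fields.extend(lut[codes, np.arange(ds.n_snps)])
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# PLINK binary (.bed/.bim/.fam)
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit codes, SNP-major: 00=hom A1 (dose 2), 01=missing, 10=het, 11=hom A2
_CODE_TO_DOSE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSE_TO_CODE = {2: 0, -1: 1, 1: 2, 0: 3}


def _read_binary(prefix: Path) -> GenotypeDataset:
    bim = pd.read_csv(
        _ext(prefix, ".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": int, "snp_id": str, "pos": int, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        _ext(prefix, ".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)
    raw = Path(_ext(prefix, ".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes (not SNP-major v1.00)")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if len(body) != bytes_per_snp * m:
        raise FormatError(
            f"{prefix}.bed: {len(body)} data bytes, expected "
            f"{bytes_per_snp * m} for {n} animals x {m} SNPs")
    mat = body.reshape(m, bytes_per_snp)
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (mat >> (2 * k)) & 0b11
    geno = _CODE_TO_DOSE[codes[:, :n]].T.copy()
    snps = bim[["snp_id", "chrom", "pos", "a1", "a2"]]
    animals = pd.DataFrame(
        {"animal_id": fam["iid"], "breed": fam["fid"], "group": ""})
    return GenotypeDataset(geno, animals, snps)


def _write_binary(ds: GenotypeDataset, prefix: Path) -> None:
    with open(_ext(prefix, ".bim"), "w") as fh:
        for _, s in ds.snps.iterrows():
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos}\t{s.a1}\t{s.a2}\n")
    with open(_ext(prefix, ".fam"), "w") as fh:
        for _, a in ds.animals.iterrows():
            fh.write(f"{a.breed or a.animal_id}\t{a.animal_id}\t0\t0\t0\t-9\n")
    n, m = ds.n_animals, ds.n_snps
    bytes_per_snp = (n + 3) // 4
    codes = np.ones((m, bytes_per_snp * 4), dtype=np.uint8)  # pad = 01? no: 00
    codes[:, :] = 0
    dose = ds.genotypes.T.astype(np.int64)  # m x n
    code_lut = np.zeros(4, dtype=np.uint8)
    for d, c in _DOSE_TO_CODE.items():
        code_lut[d + 1] = c
    codes[:, :n] = code_lut[dose + 1]
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= codes[:, k::4] << (2 * k)
    with open(_ext(prefix, ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# public IO API
# ---------------------------------------------------------------------------

def read_plink(
    path_prefix: str | Path,
    format: str = "auto",
    groups: dict[str, str] | str | Path | None = None,
) -> GenotypeDataset:
    """Read a PLINK fileset into a :class:`GenotypeDataset`.

    Parameters
    ----------
    path_prefix:
        Path without extension; ``.ped``/``.map`` or ``.bed``/``.bim``/``.fam``
        must exist next to it.
    format:
        ``"text"``, ``"binary"`` or ``"auto"`` (binary preferred if present).
    groups:
        Optional breed -> group mapping (dict, or path to a two-column TSV
        with header ``breed\tgroup``).  PLINK files carry no group notion;
        the family ID column is used as the breed code.
    """
    prefix = Path(path_prefix)
    if format == "auto":
        format = "binary" if _ext(prefix, ".bed").exists() else "text"
    if format == "text":
        ds = _read_text(prefix)
    elif format == "binary":
        ds = _read_binary(prefix)
    else:
        raise ValueError(f"unknown format {format!r}")
    if groups is not None:
        if not isinstance(groups, dict):
            gdf = pd.read_csv(groups, sep="\t", dtype=str)
            groups = dict(zip(gdf.iloc[:, 0], gdf.iloc[:, 1]))
        ds = ds.with_groups(groups)
    return ds


def write_plink(ds: GenotypeDataset, path_prefix: str | Path,
                format: str = "binary") -> None:
    """Write the dataset as a PLINK text or binary fileset (lossless for
    binary; text preserves dosages under the first-encountered-allele
    reading convention)."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if format == "text":
        _write_text(ds, prefix)
    elif format == "binary":
        _write_binary(ds, prefix)
    else:
        raise ValueError(f"unknown format {format!r}")


def write_groups(ds: GenotypeDataset, path: str | Path) -> None:
    """Write the breed -> group mapping as a two-column TSV."""
    bg = ds.animals[["breed", "group"]].drop_duplicates().sort_values("breed")
    bg.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one (the Wigginton/PLINK convention).  Returns p in (0, 1].
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotyped animals")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa  # rare-allele count
    # heterozygote counts share parity with n_rare
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    if len(hets) == 0:
        return 1.0
    # log P(het = h | allele counts) up to a constant:
    # multinomial coefficient x 2^h  (Levene's conditional distribution)
    homr = (n_rare - hets) // 2
    homc = n - hets - homr
    logp = (
        hets * math.log(2.0)
        - _lgamma_arr(hets + 1) - _lgamma_arr(homr + 1) - _lgamma_arr(homc + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.nonzero(hets == n_Aa)[0][0]]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def _lgamma_arr(x: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln
    return gammaln(x.astype(np.float64))


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

@dataclass
class QCParams:
    """Thresholds for the fixed-order QC filters.

    Call rates are strict inequalities ("larger than"); MAF is inclusive
    (kept when MAF >= min_maf); a SNP is removed when its HWE exact p-value
    is strictly below ``hwe_p_threshold``.
    """

    min_call_rate_animal: float = 0.95
    min_call_rate_snp: float = 0.95
    min_maf: float = 0.05
    hwe_p_threshold: float = 1e-6
    drop_unmapped: bool = True
    hwe_per_breed: bool = False

    def __post_init__(self) -> None:
        for name in ("min_call_rate_animal", "min_call_rate_snp", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.hwe_p_threshold <= 1.0:
            raise ValueError("hwe_p_threshold must lie in [0, 1]")


@dataclass
class QCReport:
    """Per-filter removal counts, in application order."""

    n_animals_in: int = 0
    n_snps_in: int = 0
    snps_unmapped: int = 0
    animals_call_rate: int = 0
    snps_call_rate: int = 0
    snps_maf: int = 0
    snps_hwe: int = 0
    n_animals_out: int = 0
    n_snps_out: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input_animals", self.n_animals_in),
            ("input_snps", self.n_snps_in),
            ("removed_snps_unmapped", self.snps_unmapped),
            ("removed_animals_call_rate", self.animals_call_rate),
            ("removed_snps_call_rate", self.snps_call_rate),
            ("removed_snps_maf", self.snps_maf),
            ("removed_snps_hwe", self.snps_hwe),
            ("retained_animals", self.n_animals_out),
            ("retained_snps", self.n_snps_out),
        ]
        return pd.DataFrame(rows, columns=["step", "count"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def apply_qc(ds: GenotypeDataset,
             params: QCParams | None = None) -> tuple[GenotypeDataset, QCReport]:
    """Apply the QC filters in fixed order and report per-step removals.

    Order: (1) unmapped SNPs, (2) animal call rate, (3) SNP call rate,
    (4) MAF on remaining animals, (5) HWE exact test on the pooled remaining
    animals.  Raises :class:`QCError` if no animal or no SNP survives.
    """
    params = params or QCParams()
    rep = QCReport(n_animals_in=ds.n_animals, n_snps_in=ds.n_snps)

    snp_keep = np.ones(ds.n_snps, dtype=bool)
    if params.drop_unmapped:
        mapped = (ds.snps["chrom"].to_numpy() > 0) & (ds.snps["pos"].to_numpy() > 0)
        rep.snps_unmapped = int((~mapped).sum())
        snp_keep &= mapped
    ds = ds.subset(snp_idx=np.nonzero(snp_keep)[0])

    called = ~ds.missing_mask()
    if ds.n_snps > 0:
        animal_cr = called.mean(axis=1)
    else:
        animal_cr = np.ones(ds.n_animals)
    a_keep = animal_cr > params.min_call_rate_animal
    rep.animals_call_rate = int((~a_keep).sum())
    ds = ds.subset(animal_idx=np.nonzero(a_keep)[0])
    if ds.n_animals == 0:
        raise QCError("no animals left after call-rate filter")

    called = ~ds.missing_mask()
    snp_cr = called.mean(axis=0)
    s_keep = snp_cr > params.min_call_rate_snp
    rep.snps_call_rate = int((~s_keep).sum())
    ds = ds.subset(snp_idx=np.nonzero(s_keep)[0])

    freq = ds.allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    with np.errstate(invalid="ignore"):
        s_keep = ~(maf < params.min_maf)  # NaN (uncalled) passes through
    rep.snps_maf = int((~s_keep).sum())
    ds = ds.subset(snp_idx=np.nonzero(s_keep)[0])

    if params.hwe_p_threshold > 0 and ds.n_snps > 0:
        g = ds.genotypes
        n_hom2 = (g == 2).sum(axis=0)  # A1/A1
        n_het = (g == 1).sum(axis=0)
        n_hom0 = (g == 0).sum(axis=0)
        pvals = np.array([
            hwe_exact_test(int(a), int(h), int(b)) if a + h + b > 0 else 1.0
            for a, h, b in zip(n_hom2, n_het, n_hom0)
        ])
        s_keep = pvals >= params.hwe_p_threshold
        rep.snps_hwe = int((~s_keep).sum())
        ds = ds.subset(snp_idx=np.nonzero(s_keep)[0])

    if ds.n_snps == 0:
        raise QCError("no SNPs left after QC")
    rep.n_animals_out = ds.n_animals
    rep.n_snps_out = ds.n_snps
    return ds, rep
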