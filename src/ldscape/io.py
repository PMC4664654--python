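"""Genotype I/O: PLINK binary filesets and plain-text genotype tables.

The in-memory container is :class:`GenotypeMatrix`: a samples x SNPs matrix of
genotype codes counting copies of **allele2** (the second allele column of the
.bim file, PLINK's A2).  This convention is load-bearing: the sign of the
two-locus correlation ``r`` produced downstream refers to the allele2/allele2
haplotype, so swapping allele1/allele2 at one locus flips the sign of ``r``.

Missing genotypes are coded ``MISSING`` (= -1).  Coordinates are 1-based
inclusive base pairs (.bim convention); all inter-marker distances used
downstream are plain ``pos_bp`` differences.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING: int = -1

#: Bovine autosomes; non-autosomal markers are dropped at load time.
BOVINE_AUTOSOMES: frozenset[int] = frozenset(range(1, 30))

_PLINK_MAGIC = b"\x6c\x1b"
_SNP_MAJOR = 0x01

# 2-bit PLINK code -> genotype code (count of allele2)
# 0b00 hom allele1 -> 0 ; 0b01 missing ; 0b10 het -> 1 ; 0b11 hom allele2 -> 2
_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_ENCODE = {0: 0b00, 1: 0b10, 2: 0b11, MISSING: 0b01}

MARKER_COLUMNS = ["chrom", "id", "pos_bp", "allele1", "allele2"]


class PlinkFormatError(ValueError):
    """Malformed PLINK binary input (bad magic, unsupported mode, bad length)."""


@dataclass(frozen=True)
class MarkerRecord:
    """One SNP of the marker map."""

    chrom: int
    id: str
    pos_bp: int
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"pos_bp must be >= 1, got {self.pos_bp} for {self.id}")
        if self.allele1 == self.allele2:
            raise ValueError(f"alleles must differ at marker {self.id}")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs diploid genotype codes with marker map and labels.

    Parameters
    ----------
    genotypes
        int8 array of shape (n_samples, n_snps); entries in {0, 1, 2, MISSING},
        counting copies of allele2.
    markers
        DataFrame with columns chrom, id, pos_bp, allele1, allele2, sorted by
        (chrom, pos_bp).
    sample_ids
        Unique sample identifiers, one per row.
    population
        Optional per-sample population label (array of str), same length as
        ``sample_ids``.
    """

    genotypes: np.ndarray
    markers: pd.DataFrame
    sample_ids: list[str]
    population: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x SNPs)")
        if list(self.markers.columns[:5]) != MARKER_COLUMNS:
            self.markers = self.markers[MARKER_COLUMNS].copy()
        self.markers = self.markers.reset_index(drop=True)
        n_samples, n_snps = self.genotypes.shape
        if len(self.markers) != n_snps:
            raise ValueError(
                f"marker table has {len(self.markers)} rows for {n_snps} SNP columns"
            )
        if len(self.sample_ids) != n_samples:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n_samples} genotype rows"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, MISSING}")
        chrom = self.markers["chrom"].to_numpy()
        pos = self.markers["pos_bp"].to_numpy()
        order = np.lexsort((pos, chrom))
        if not np.array_equal(order, np.arange(n_snps)):
            raise ValueError("markers must be sorted by (chrom, pos_bp)")
        if self.population is not None:
            self.population = np.asarray(self.population, dtype=object)
            if len(self.population) != n_samples:
                raise ValueError("population labels do not match sample count")

    # -- conveniences -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def marker_records(self) -> list[MarkerRecord]:
        return [
            MarkerRecord(int(r.chrom), str(r.id), int(r.pos_bp), str(r.allele1), str(r.allele2))
            for r in self.markers.itertuples(index=False)
        ]

    def subset(
        self,
        samples: Sequence[int] | np.ndarray | None = None,
        snps: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Return a copy restricted to the given sample/SNP integer indices."""
        s_idx = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        m_idx = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        return GenotypeMatrix(
            genotypes=self.genotypes[np.ix_(s_idx, m_idx)].copy(),
            markers=self.markers.iloc[m_idx].reset_index(drop=True),
            sample_ids=[self.sample_ids[i] for i in s_idx],
            population=None if self.population is None else self.population[s_idx],
        )

    def split_by_population(self) -> dict[str, "GenotypeMatrix"]:
        """One single-population matrix per distinct label, label-sorted."""
        if self.population is None:
            raise ValueError("population labels are not set")
        out: dict[str, GenotypeMatrix] = {}
        for pop in sorted(set(self.population)):
            idx = np.flatnonzero(self.population == pop)
            out[pop] = self.subset(samples=idx)
        return out


# ---------------------------------------------------------------------------
# PLINK binary fileset
# ---------------------------------------------------------------------------

def _read_bim(path: Path, autosomes: frozenset[int]) -> tuple[pd.DataFrame, np.ndarray]:
    bim = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos_bp", "allele1", "allele2"],
        dtype={"id": str, "allele1": str, "allele2": str},
    )
    chrom_num = pd.to_numeric(bim["chrom"], errors="coerce")
    keep = chrom_num.isin(list(autosomes)).to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d non-autosomal or unparseable-chromosome SNPs", n_dropped)
    bim = bim.loc[keep].copy()
    bim["chrom"] = chrom_num[keep].astype(int)
    markers = bim[["chrom", "id", "pos_bp", "allele1", "allele2"]].reset_index(drop=True)
    return markers, keep


def read_plink(
    prefix: str | Path,
    autosomes: frozenset[int] = BOVINE_AUTOSOMES,
) -> GenotypeMatrix:
    """Read a PLINK ``prefix.bed/.bim/.fam`` fileset (SNP-major .bed only).

    Non-autosomal markers are dropped with a logged count.  The family-ID
    column of the .fam file is used as the population label.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n_samples = len(fam)
    markers, keep = _read_bim(prefix.with_suffix(".bim"), autosomes)
    n_snps_file = len(keep)

    data = prefix.with_suffix(".bed").read_bytes()
    if data[:2] != _PLINK_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed does not start with PLINK magic bytes")
    if len(data) < 3 or data[2] != _SNP_MAJOR:
        raise PlinkFormatError(
            f"{prefix}.bed is not SNP-major (mode byte {data[2] if len(data) > 2 else 'absent'})"
        )
    bytes_per_snp = (n_samples + 3) // 4
    expected = 3 + n_snps_file * bytes_per_snp
    if len(data) != expected:
        raise PlinkFormatError(
            f"{prefix}.bed has {len(data)} bytes, expected {expected} "
            f"for {n_samples} samples x {n_snps_file} SNPs"
        )
    raw = np.frombuffer(data, dtype=np.uint8, offset=3).reshape(n_snps_file, bytes_per_snp)
    # unpack the four 2-bit fields of each byte, lowest bits = first sample
    two_bit = np.stack([(raw >> s) & 0b11 for s in (0, 2, 4, 6)], axis=2)
    two_bit = two_bit.reshape(n_snps_file, -1)[:, :n_samples]
    genotypes = _DECODE[two_bit].T  # samples x SNPs
    genotypes = genotypes[:, keep]

    return GenotypeMatrix(
        genotypes=np.ascontiguousarray(genotypes),
        markers=markers,
        sample_ids=fam["iid"].tolist(),
        population=fam["fid"].to_numpy(dtype=object),
    )


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``g`` as ``prefix.bed/.bim/.fam`` (SNP-major, trailing bits zero).

    The population label goes into the family-ID column of the .fam file;
    the .bim genetic-distance column is written as 0.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n_samples, n_snps = g.genotypes.shape

    bim = g.markers.copy()
    bim.insert(2, "cm", 0)
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    pops = g.population if g.population is not None else np.array(["POP1"] * n_samples, dtype=object)
    fam = pd.DataFrame(
        {
            "fid": pops,
            "iid": g.sample_ids,
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    bytes_per_snp = (n_samples + 3) // 4
    codes = np.empty((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    codes[:] = 0  # trailing pad bits encode as 0b00
    encode_lut = np.zeros(4, dtype=np.uint8)
    for code, bits in _ENCODE.items():
        encode_lut[code % 4] = bits  # MISSING (-1) -> index 3
    codes[:, :n_samples] = encode_lut[g.genotypes.T % 4]
    codes = codes.reshape(n_snps, bytes_per_snp, 4)
    packed = (
        codes[:, :, 0]
        | (codes[:, :, 1] << 2)
        | (codes[:, :, 2] << 4)
        | (codes[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_PLINK_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Plain-text genotype table (hand-written fixtures)
# ---------------------------------------------------------------------------

def write_genotype_table(g: GenotypeMatrix, geno_path: str | Path, map_path: str | Path) -> None:
    """Write a TSV genotype table plus a marker-map TSV.

    The genotype table has columns ``sample_id``, ``population``, then one
    column per SNP id with codes 0/1/2/NA; the map has the marker columns.
    """
    codes = g.genotypes.astype(object)
    codes[g.genotypes == MISSING] = "NA"
    df = pd.DataFrame(codes, columns=g.markers["id"], index=g.sample_ids)
    df.insert(0, "population", g.population if g.population is not None else "POP1")
    df.index.name = "sample_id"
    df.to_csv(geno_path, sep="\t")
    g.markers.to_csv(map_path, sep="\t", index=False)


def read_genotype_table(geno_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read the TSV pair written by :func:`write_genotype_table`."""
    markers = pd.read_csv(map_path, sep="\t", dtype={"id": str, "allele1": str, "allele2": str})
    df = pd.read_csv(
        geno_path, sep="\t", index_col="sample_id", dtype=str, keep_default_na=False
    )
    pops = df.pop("population").to_numpy(dtype=object)
    raw = df[markers["id"]].to_numpy(dtype=object)
    geno = np.where(raw == "NA", MISSING, raw).astype(np.int8)
    return GenotypeMatrix(
        genotypes=geno,
        markers=markers,
        sample_ids=[str(s) for s in df.index],
        population=pops,
    )


def attach_populations(
    g: GenotypeMatrix, labels: Mapping[str, str] | pd.Series | pd.DataFrame
) -> GenotypeMatrix:
    """Return a copy of ``g`` with the population field set from ``labels``.

    ``labels`` maps sample_id -> population (a dict, Series indexed by sample
    id, or two-column DataFrame).  Every sample must be present exactly once.
    """
    if isinstance(labels, pd.DataFrame):
        if labels.iloc[:, 0].duplicated().any():
            dupes = labels.iloc[:, 0][labels.iloc[:, 0].duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in label table: {dupes}")
        labels = pd.Series(
            labels.iloc[:, 1].to_numpy(), index=labels.iloc[:, 0].astype(str)
        )
    if isinstance(labels, pd.Series):
        if labels.index.duplicated().any():
            raise ValueError("duplicate sample ids in label table")
        labels = labels.to_dict()
    missing = [s for s in g.sample_ids if s not in labels]
    if missing:
        raise ValueError(f"samples missing from label table: {missing}")
    pops = np.array([labels[s] for s in g.sample_ids], dtype=object)
    return replace(g, genotypes=g.genotypes.copy(), population=pops)


def read_population_labels(path: str | Path) -> pd.Series:
    """Read a two-column (sample_id, population) TSV, with or without header."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "population"]:
        df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "population"], dtype=str)
    return pd.Series(df["population"].to_numpy(), index=df["sample_id"])
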