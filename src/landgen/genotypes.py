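"""Genotype matrices: container, SNP filters, and VCF 4.2 round-trip.

Genotypes are biallelic diploid dosages of the alternate allele
(0/1/2) with ``-1`` as the missing sentinel, individuals in rows and
loci in columns. Population labels and geographic coordinates travel
with the matrix so that downstream statistics never need side lookups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class Locus:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str = "A"
    alt: str = "T"

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass
class GenotypeMatrix:
    """Individuals x loci alt-allele dosage matrix with sample metadata."""

    genotypes: np.ndarray
    loci: list[Locus]
    individual_ids: list[str]
    populations: list[str]
    lat: np.ndarray
    lon: np.ndarray
    ground_truth: object | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        n_ind, n_loci = self.genotypes.shape
        if len(self.loci) != n_loci:
            raise ValueError("locus metadata does not match matrix width")
        if not (len(self.individual_ids) == len(self.populations) == len(self.lat) == len(self.lon) == n_ind):
            raise ValueError("sample metadata does not match matrix height")
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotypes must be 0/1/2 or missing (-1)")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def locus_ids(self) -> list[str]:
        return [l.id for l in self.loci]

    def population_names(self) -> list[str]:
        """Unique population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def population_index(self) -> dict[str, np.ndarray]:
        pops = np.asarray(self.populations)
        return {p: np.flatnonzero(pops == p) for p in self.population_names()}

    def missing_fraction(self) -> np.ndarray:
        """Per-locus fraction of missing genotypes."""
        return (self.genotypes == MISSING).mean(axis=0)

    def minor_allele_frequency(self) -> np.ndarray:
        """Per-locus MAF over non-missing genotypes (NaN if all missing)."""
        g = np.ma.masked_equal(self.genotypes, MISSING)
        p = g.mean(axis=0).filled(np.nan) / 2.0
        return np.minimum(p, 1.0 - p)

    def population_frequencies(self) -> pd.DataFrame:
        """Alt-allele frequency per population (rows) x locus (columns)."""
        rows = {}
        for pop, idx in self.population_index().items():
            g = np.ma.masked_equal(self.genotypes[idx], MISSING)
            rows[pop] = (g.mean(axis=0) / 2.0).filled(np.nan)
        return pd.DataFrame.from_dict(rows, orient="index", columns=self.locus_ids)

    def population_coords(self) -> pd.DataFrame:
        """Mean lat/lon per population."""
        df = pd.DataFrame({"population": self.populations, "lat": self.lat, "lon": self.lon})
        return df.groupby("population", sort=False).mean()

    def imputed(self) -> np.ndarray:
        """Float matrix with missing entries replaced by the locus mean."""
        g = self.genotypes.astype(float)
        miss = self.genotypes == MISSING
        g[miss] = np.nan
        means = np.nanmean(np.where(miss, np.nan, g), axis=0)
        means = np.where(np.isnan(means), 0.0, means)
        return np.where(miss, means[None, :], g)

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self,
            genotypes=self.genotypes[:, keep],
            loci=[self.loci[i] for i in keep],
        )

    def subset_individuals(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self,
            genotypes=self.genotypes[keep],
            individual_ids=[self.individual_ids[i] for i in keep],
            populations=[self.populations[i] for i in keep],
            lat=self.lat[keep],
            lon=self.lon[keep],
        )


@dataclass
class FilterReport:
    n_input: int
    n_removed_missing: int
    n_removed_maf: int
    n_retained: int


class EmptyResultError(ValueError):
    """All loci were removed by a filter."""


def filter_snps(
    raw: GenotypeMatrix, max_missing: float = 0.4, min_maf: float = 0.01
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop loci with missing fraction >= max_missing or MAF <= min_maf.

    Mirrors the standard hard-filter step for reduced-representation SNP
    panels (biallelic sites, missingness and minor-allele-frequency
    thresholds). The missing filter is applied first; the MAF filter is
    then evaluated on the survivors.
    """
    miss = raw.missing_fraction()
    keep_miss = miss < max_missing
    n_removed_missing = int((~keep_miss).sum())
    maf = raw.minor_allele_frequency()
    with np.errstate(invalid="ignore"):
        keep_maf = np.where(np.isnan(maf), False, maf > min_maf)
    keep = keep_miss & keep_maf
    n_removed_maf = int((keep_miss & ~keep_maf).sum())
    if not keep.any():
        raise EmptyResultError("all loci removed by filters")
    report = FilterReport(raw.n_loci, n_removed_missing, n_removed_maf, int(keep.sum()))
    return raw.subset_loci(keep), report


# ----------------------------------------------------------------- VCF I/O


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write biallelic diploid genotypes as an uncompressed VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(l.chrom for l in g.loci):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.individual_ids) + "\n")
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, locus in enumerate(g.loci):
            calls = "\t".join(gt_codes[int(v)] for v in g.genotypes[:, j])
            fh.write(
                f"{locus.chrom}\t{locus.pos}\t{locus.id}\t{locus.ref}\t{locus.alt}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_vcf(
    path: str | Path,
    samples: pd.DataFrame | str | Path | None = None,
) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into a :class:`GenotypeMatrix`.

    ``samples`` is an optional table (or CSV path) with columns
    ``id, population, lat, lon``; samples missing from it get population
    ``"pop0"`` and coordinates 0. Multi-allelic records are rejected.
    Half-calls and ``./.`` become missing; phasing is ignored.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    genotypes = []
    loci = []
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            raise ValueError(f"record {i + 1} ({rec.CHROM}:{rec.POS}): multi-allelic records not supported")
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        types = rec.gt_types
        dosage = np.select([types == 0, types == 1, types == 3], [0, 1, 2], default=MISSING)
        genotypes.append(dosage.astype(np.int16))
        loci.append(Locus(rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    if not loci:
        raise ValueError(f"{path}: no usable records")
    mat = np.stack(genotypes, axis=1)

    if samples is None:
        meta = pd.DataFrame({"id": sample_ids, "population": "pop0", "lat": 0.0, "lon": 0.0})
    else:
        meta = samples if isinstance(samples, pd.DataFrame) else pd.read_csv(samples)
        meta = meta.set_index("id").reindex(sample_ids).reset_index()
        if meta["population"].isna().any():
            missing = meta.loc[meta["population"].isna(), "id"].tolist()
            raise ValueError(f"samples table missing entries for {missing}")
    return GenotypeMatrix(
        mat,
        loci,
        sample_ids,
        meta["population"].astype(str).tolist(),
        meta["lat"].to_numpy(float),
        meta["lon"].to_numpy(float),
    )


def write_samples_csv(g: GenotypeMatrix, path: str | Path) -> None:
    pd.DataFrame(
        {"id": g.individual_ids, "population": g.populations, "lat": g.lat, "lon": g.lon}
    ).to_csv(path, index=False)
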