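"""VCF input/output for allelic read-depth data.

The only genotype information this package consumes is the AD FORMAT field
(allelic depths, REF count first).  Any GT/PL/DP fields present in the
input are ignored: genotypes are re-derived from the read counts.  Marker
coordinates are carried through verbatim but never interpreted — the
method requires neither ordered markers nor a reference panel, so
chromosome and position are opaque labels.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
import pysam

__all__ = [
    "Site",
    "ReadCountMatrix",
    "VcfFormatError",
    "VcfParseError",
    "read_vcf",
    "write_vcf",
]

_GT_FOR = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


class VcfFormatError(ValueError):
    """The VCF lacks a required feature (e.g. no AD FORMAT declaration)."""


class VcfParseError(ValueError):
    """A VCF record could not be parsed."""


@dataclass(frozen=True)
class Site:
    """One biallelic SNP.  chrom/pos are labels only, never ordering keys."""

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"site {self.id}: REF and ALT alleles are identical")


@dataclass
class ReadCountMatrix:
    """samples x sites grid of (reference, alternate) read counts.

    The sole raw input of the pipeline.  ``ref`` and ``alt`` are integer
    arrays of shape (n_samples, n_sites); a genotype entry with no data is
    stored as (0, 0), which the binomial likelihood treats identically to
    zero observed reads.
    """

    samples: list[str]
    sites: list[Site]
    ref: np.ndarray
    alt: np.ndarray
    n_dropped_sites: int = 0

    def __post_init__(self) -> None:
        self.ref = np.asarray(self.ref, dtype=np.int64)
        self.alt = np.asarray(self.alt, dtype=np.int64)
        shape = (len(self.samples), len(self.sites))
        if self.ref.shape != shape or self.alt.shape != shape:
            raise ValueError(
                f"count arrays must have shape {shape}, got {self.ref.shape} / {self.alt.shape}"
            )
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("read counts must be non-negative")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample names must be unique")
        if len({s.id for s in self.sites}) != len(self.sites):
            raise ValueError("site ids must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def depth(self) -> np.ndarray:
        """Total reads per (sample, site) entry."""
        return self.ref + self.alt

    def subset(self, sample_idx=None, site_idx=None) -> "ReadCountMatrix":
        """A new matrix restricted to the given sample/site index arrays."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_sites) if site_idx is None else np.asarray(site_idx)
        return ReadCountMatrix(
            samples=[self.samples[i] for i in si],
            sites=[self.sites[j] for j in vi],
            ref=self.ref[np.ix_(si, vi)],
            alt=self.alt[np.ix_(si, vi)],
        )


def _is_snp_allele(a) -> bool:
    return isinstance(a, str) and len(a) == 1 and a.upper() in "ACGT"


def read_vcf(path) -> ReadCountMatrix:
    """Load a multi-sample VCF into a :class:`ReadCountMatrix`.

    Only biallelic SNP records are retained; records with more than one ALT
    allele or with non-SNP alleles are dropped and tallied in
    ``n_dropped_sites``.  A genotype whose AD is missing maps to (0, 0).

    Raises
    ------
    VcfFormatError
        If the header declares no AD FORMAT field.
    VcfParseError
        If a record cannot be parsed (the record number is reported).
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    with vf:
        if "AD" not in vf.header.formats:
            raise VcfFormatError(f"{path}: header declares no AD FORMAT field")
        samples = list(vf.header.samples)
        sites: list[Site] = []
        ref_rows: list[list[int]] = []
        alt_rows: list[list[int]] = []
        dropped = 0
        seen_ids: set[str] = set()
        recno = 0
        records = iter(vf)
        while True:
            try:
                rec = next(records)
            except StopIteration:
                break
            except (OSError, ValueError) as exc:
                raise VcfParseError(
                    f"{path}: malformed VCF record #{recno + 1}: {exc}"
                ) from exc
            recno += 1
            alts = rec.alts or ()
            if len(alts) != 1 or not _is_snp_allele(rec.ref) or not _is_snp_allele(alts[0]):
                dropped += 1
                continue
            sid = rec.id if rec.id not in (None, ".") else f"{rec.chrom}_{rec.pos}"
            if sid in seen_ids:
                sid = f"{sid}_{recno}"
            seen_ids.add(sid)
            sites.append(Site(sid, str(rec.chrom), int(rec.pos), rec.ref, alts[0]))
            rrow: list[int] = []
            arow: list[int] = []
            for name in samples:
                ad = rec.samples[name].get("AD")
                if ad is None or len(ad) < 2 or ad[0] is None or ad[1] is None:
                    rrow.append(0)
                    arow.append(0)
                else:
                    rrow.append(int(ad[0]))
                    arow.append(int(ad[1]))
            ref_rows.append(rrow)
            alt_rows.append(arow)
    n_sites = len(sites)
    ref = np.array(ref_rows, dtype=np.int64).T if n_sites else np.zeros((len(samples), 0), np.int64)
    alt = np.array(alt_rows, dtype=np.int64).T if n_sites else np.zeros((len(samples), 0), np.int64)
    return ReadCountMatrix(samples, sites, ref, alt, n_dropped_sites=dropped)


def write_vcf(matrix: ReadCountMatrix, calls: np.ndarray, path, meta: dict | None = None) -> None:
    """Write called genotypes and their probabilities to a VCF.

    ``calls`` has shape (n_samples, n_sites, 3): the called genotype
    probability triple per entry.  GT is the argmax genotype (ties break to
    the lower genotype index, so output is deterministic), original AD
    pairs are preserved, and the triple is emitted in a 3-float GP FORMAT
    field rounded to 3 decimals.  ``meta`` key/value pairs are recorded as
    header lines documenting the run.
    """
    calls = np.asarray(calls, dtype=float)
    if calls.shape != (matrix.n_samples, matrix.n_sites, 3):
        raise ValueError(
            f"calls must have shape {(matrix.n_samples, matrix.n_sites, 3)}, got {calls.shape}"
        )
    header = pysam.VariantHeader()
    header.add_line("##source=gbsimpute")
    for key, val in (meta or {}).items():
        header.add_line(f"##gbsimpute_{key}={val}")
    for chrom in dict.fromkeys(s.chrom for s in matrix.sites):
        header.add_line(f"##contig=<ID={chrom}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Called genotype">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (REF,ALT)">')
    header.add_line(
        '##FORMAT=<ID=GP,Number=3,Type=Float,Description='
        '"Called genotype probabilities for 0/0, 0/1, 1/1">'
    )
    for name in matrix.samples:
        header.add_sample(name)
    gt = np.argmax(calls, axis=-1)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, site in enumerate(matrix.sites):
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                stop=site.pos,
                alleles=(site.ref_allele, site.alt_allele),
                id=site.id,
            )
            for i, name in enumerate(matrix.samples):
                fmt = rec.samples[name]
                fmt["GT"] = _GT_FOR[int(gt[i, j])]
                fmt["AD"] = (int(matrix.ref[i, j]), int(matrix.alt[i, j]))
                fmt["GP"] = tuple(round(float(p), 3) for p in calls[i, j])
            out.write(rec)
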