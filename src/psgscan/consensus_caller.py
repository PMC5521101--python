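"""Reference-anchored consensus calling from read pileups.

Reproduces a threshold-rule diploid caller: reads are dropped unless
properly paired with mapping quality >= 25 (one representative per
duplicate group, the highest-mapping-quality read, is retained); a site
is called when it has >= 8 filtered reads, alleles count when their
frequency among retained reads is >= 0.125 (1/8, compared in exact
integer arithmetic); two passing alleles give a two-base IUPAC code,
one gives the base, anything else gives N.  Deletion-spanning sites are
missing data (N) and insertions relative to the reference are ignored.
Reference coordinates of missing/indel runs are recorded for the
downstream positional-artifact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import genetic_code as gc
from .io_formats import CodonAlignment, GeneModel

logger = logging.getLogger(__name__)

MIN_MAPQ = 25
MIN_COVERAGE = 8
MIN_ALLELE_FREQ_NUM = 1   # allele frequency threshold as the exact
MIN_ALLELE_FREQ_DEN = 8   # fraction 1/8 = 0.125

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
COMPLEMENT = str.maketrans("ACGTRYSWKMN-", "TGCAYRSWMKN-")


def encode_bases(bases) -> np.ndarray:
    """'ACGT' letters -> int8 codes 0..3."""
    if isinstance(bases, np.ndarray) and bases.dtype.kind in "iu":
        return bases.astype(np.int8)
    arr = np.frombuffer("".join(bases).encode(), dtype=np.uint8)
    codes = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        codes[b] = i
    out = codes[arr]
    if (out < 0).any():
        raise ValueError("pileup bases must be A, C, G or T")
    return out


# ---------------------------------------------------------------------------
# Containers

@dataclass
class PileupColumn:
    """One reference site in one species: the retained reads' bases,
    mapping qualities, proper-pair flags and duplicate-group ids
    (-1 = not a duplicate), plus a deletion marker."""

    seq_id: str
    pos: int
    bases: np.ndarray
    mapq: np.ndarray
    proper: np.ndarray
    dup_group: np.ndarray
    deletion: bool = False

    def __post_init__(self):
        self.bases = encode_bases(self.bases)
        self.mapq = np.asarray(self.mapq, dtype=np.int32)
        self.proper = np.asarray(self.proper, dtype=bool)
        self.dup_group = np.asarray(self.dup_group, dtype=np.int64)

    @property
    def coverage(self) -> int:
        return len(self.bases)


@dataclass
class GenePileup:
    """All reads of one species over one gene's CDS span, flattened:
    ``read_site`` indexes into ``positions`` (ascending reference
    coordinates of CDS bases)."""

    gene_id: str
    species: str
    seq_id: str
    positions: np.ndarray
    read_site: np.ndarray
    read_base: np.ndarray
    read_mapq: np.ndarray
    read_proper: np.ndarray
    read_dup: np.ndarray
    deletion: np.ndarray  # bool per position

    def column(self, site: int) -> PileupColumn:
        m = self.read_site == site
        return PileupColumn(self.seq_id, int(self.positions[site]),
                            self.read_base[m], self.read_mapq[m],
                            self.read_proper[m], self.read_dup[m],
                            deletion=bool(self.deletion[site]))


@dataclass
class CallStats:
    """Per gene x species calling statistics."""

    gene_id: str
    species: str
    total_base_calls: int = 0
    n_duplicates_removed: int = 0
    n_heterozygous: int = 0
    het_frequencies: list[float] = field(default_factory=list)
    n_multiallelic_sites: int = 0
    coverage: Optional[np.ndarray] = None
    mean_coverage: float = 0.0
    #: reference intervals (0-based half-open) of N/indel runs
    missing_runs: list[tuple[int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Read filtering and base calling (single-column reference semantics)

def filter_reads(column: PileupColumn) -> PileupColumn:
    """Keep properly-paired reads with mapq >= MIN_MAPQ; within each
    duplicate group keep only the highest-mapq read."""
    keep = column.proper & (column.mapq >= MIN_MAPQ)
    bases, mapq = column.bases[keep], column.mapq[keep]
    proper, dup = column.proper[keep], column.dup_group[keep]
    sel = np.ones(len(bases), dtype=bool)
    for g in np.unique(dup[dup >= 0]):
        m = np.flatnonzero(dup == g)
        if len(m) > 1:
            best = m[np.argmax(mapq[m])]
            sel[m] = False
            sel[best] = True
    return PileupColumn(column.seq_id, column.pos, bases[sel], mapq[sel],
                        proper[sel], dup[sel], deletion=column.deletion)


def call_base(column: PileupColumn) -> str:
    """IUPAC consensus symbol for an already-filtered column."""
    symbol, _, _ = call_base_verbose(column)
    return symbol


def call_base_verbose(column: PileupColumn
                      ) -> tuple[str, Optional[float], bool]:
    """(symbol, minor allele frequency if heterozygous, multiallelic?)"""
    if column.deletion:
        return "N", None, False
    counts = np.bincount(column.bases, minlength=4)
    cov = int(counts.sum())
    if cov < MIN_COVERAGE:
        return "N", None, False
    passing = counts * MIN_ALLELE_FREQ_DEN >= cov * MIN_ALLELE_FREQ_NUM
    passing &= counts > 0
    n_pass = int(passing.sum())
    if n_pass == 1:
        return gc.NUCLEOTIDES[int(np.flatnonzero(passing)[0])], None, False
    if n_pass == 2:
        pair = frozenset(gc.NUCLEOTIDES[i] for i in np.flatnonzero(passing))
        minor = counts[passing].min() / cov
        return gc.IUPAC_2[pair], float(minor), False
    # zero passing alleles, or >2 alleles (a paralogy signal)
    return "N", None, n_pass > 2


# ---------------------------------------------------------------------------
# Vectorised gene-level calling

def _filter_gene_reads(pile: GenePileup
                       ) -> tuple[np.ndarray, np.ndarray, int]:
    """Returns (site index, base) arrays of retained reads and the
    number of duplicate reads removed."""
    keep = pile.read_proper & (pile.read_mapq >= MIN_MAPQ)
    site = pile.read_site[keep]
    base = pile.read_base[keep]
    mapq = pile.read_mapq[keep]
    dup = pile.read_dup[keep]
    is_dup = dup >= 0
    if not is_dup.any():
        return site, base, 0
    # one representative (highest mapq) per (site, dup_group)
    uniq_site, uniq_base = site[~is_dup], base[~is_dup]
    ds, db, dm, dg = site[is_dup], base[is_dup], mapq[is_dup], dup[is_dup]
    order = np.lexsort((dm, dg, ds))
    ds, db, dg = ds[order], db[order], dg[order]
    last = np.ones(len(ds), dtype=bool)
    last[:-1] = (ds[:-1] != ds[1:]) | (dg[:-1] != dg[1:])
    n_removed = int((~last).sum())
    site = np.concatenate([uniq_site, ds[last]])
    base = np.concatenate([uniq_base, db[last]])
    return site, base, n_removed


def call_gene(pile: GenePileup, ref_bases: Optional[np.ndarray] = None
              ) -> tuple[np.ndarray, CallStats]:
    """Consensus symbols (reference-strand, ascending positions) and
    statistics for one species over one gene.

    ``ref_bases`` (int codes, reference strand, ascending) lets the
    heterozygote frequency spectrum be recorded as the frequency of the
    variant (non-reference) allele, which is what the paralog skew
    filter bins; without it the minor-allele frequency is recorded.
    """
    n_sites = len(pile.positions)
    site, base, n_removed = _filter_gene_reads(pile)
    counts = np.zeros((n_sites, 4), dtype=np.int64)
    np.add.at(counts, (site, base), 1)
    cov = counts.sum(axis=1)
    passing = (counts * MIN_ALLELE_FREQ_DEN >= cov[:, None]) & (counts > 0)
    n_pass = passing.sum(axis=1)
    callable_ = (cov >= MIN_COVERAGE) & ~pile.deletion

    symbols = np.full(n_sites, "N", dtype="<U1")
    mono = callable_ & (n_pass == 1)
    if mono.any():
        symbols[mono] = np.array(list(gc.NUCLEOTIDES))[
            np.argmax(passing[mono], axis=1)]
    het = callable_ & (n_pass == 2)
    het_freqs = []
    if het.any():
        idx = np.flatnonzero(het)
        for i in idx:
            alleles = np.flatnonzero(passing[i])
            pair = frozenset(gc.NUCLEOTIDES[j] for j in alleles)
            symbols[i] = gc.IUPAC_2[pair]
            if ref_bases is not None and ref_bases[i] in alleles:
                for j in alleles:
                    if j != ref_bases[i]:
                        het_freqs.append(float(counts[i, j] / cov[i]))
            else:
                het_freqs.append(float(counts[i][passing[i]].min() / cov[i]))
    multi = callable_ & (n_pass > 2)

    stats = CallStats(
        gene_id=pile.gene_id, species=pile.species,
        total_base_calls=int((symbols != "N").sum()),
        n_duplicates_removed=n_removed,
        n_heterozygous=int(het.sum()),
        het_frequencies=het_freqs,
        n_multiallelic_sites=int(multi.sum()),
        coverage=cov,
        mean_coverage=float(cov.mean()) if n_sites else 0.0,
        missing_runs=_runs(pile.positions, (symbols == "N") | pile.deletion),
    )
    return symbols, stats


def _runs(positions: np.ndarray, mask: np.ndarray
          ) -> list[tuple[int, int]]:
    """Maximal runs of masked sites as 0-based half-open reference
    intervals (runs broken at non-contiguous positions, e.g. introns)."""
    out = []
    start = None
    prev = None
    for p, m in zip(positions, mask):
        p = int(p)
        if m:
            if start is None or (prev is not None and p != prev + 1):
                if start is not None:
                    out.append((start, prev + 1))
                start = p
            prev = p
        else:
            if start is not None:
                out.append((start, prev + 1))
                start = None
    if start is not None:
        out.append((start, prev + 1))
    return out


def build_consensus(gene: GeneModel, pileups: dict[str, GenePileup],
                    ref_cds: Optional[str] = None
                    ) -> tuple[dict[str, str], dict[str, CallStats]]:
    """Per-species in-frame consensus CDS sequences (transcription order,
    complemented on the minus strand) and calling statistics.

    ``ref_cds`` is the reference CDS in transcription order; when given,
    heterozygote frequencies are recorded relative to it.
    """
    if not gene.frame_ok:
        raise ValueError(f"gene {gene.gene_id}: CDS length {gene.cds_length} "
                         "not divisible by 3")
    ref_bases = None
    if ref_cds is not None:
        fwd = ref_cds if gene.strand == "+" else \
            ref_cds[::-1].translate(COMPLEMENT)
        ref_bases = encode_bases(fwd)
    seqs: dict[str, str] = {}
    stats: dict[str, CallStats] = {}
    for species, pile in pileups.items():
        symbols, st = call_gene(pile, ref_bases=ref_bases)
        seq = "".join(symbols)
        if gene.strand == "-":
            seq = seq[::-1].translate(COMPLEMENT)
        seqs[species] = seq
        stats[species] = st
    return seqs, stats


def consensus_alignment(gene: GeneModel, seqs: dict[str, str],
                        reference: tuple[str, str]) -> CodonAlignment:
    """Assemble the multi-species codon alignment in reference
    coordinates.  ``reference`` is (taxon name, CDS sequence) for the
    reference genome; it is listed first and must contain no N."""
    ref_name, ref_seq = reference
    if "N" in ref_seq:
        raise ValueError("reference sequence contains N")
    taxa = [ref_name] + sorted(seqs)
    sequences = [ref_seq] + [seqs[t] for t in sorted(seqs)]
    cds_pos = gene.cds_positions()
    cmap = cds_pos.reshape(-1, 3)
    return CodonAlignment(gene.gene_id, taxa, sequences, coordinate_map=cmap)


# ---------------------------------------------------------------------------
# Pileup TSV interchange (documented stand-in for BAM pileups)

PILEUP_COLUMNS = ["seq_id", "pos", "base", "mapq", "proper_pair",
                  "dup_group", "indel"]


def write_pileup_tsv(pile: GenePileup, path: Union[str, Path]) -> None:
    """One row per read (base in {A,C,G,T}); deletion-spanning positions
    additionally get a row with base '*' and indel=1.  Positions are
    1-based in the file."""
    letters = np.array(list(gc.NUCLEOTIDES))
    with open(path, "w") as fh:
        fh.write("\t".join(PILEUP_COLUMNS) + "\n")
        for i in range(len(pile.read_site)):
            pos = int(pile.positions[pile.read_site[i]]) + 1
            fh.write(f"{pile.seq_id}\t{pos}\t"
                     f"{letters[pile.read_base[i]]}\t"
                     f"{int(pile.read_mapq[i])}\t"
                     f"{int(pile.read_proper[i])}\t"
                     f"{int(pile.read_dup[i])}\t0\n")
        for site in np.flatnonzero(pile.deletion):
            pos = int(pile.positions[site]) + 1
            fh.write(f"{pile.seq_id}\t{pos}\t*\t0\t0\t-1\t1\n")


CALLSTATS_COLUMNS = ["gene_id", "species", "total_base_calls",
                     "n_duplicates_removed", "n_heterozygous",
                     "n_multiallelic_sites", "mean_coverage",
                     "het_frequencies", "missing_runs"]


def callstats_frame(stats: Sequence[CallStats]) -> pd.DataFrame:
    rows = []
    for st in stats:
        rows.append(dict(
            gene_id=st.gene_id, species=st.species,
            total_base_calls=st.total_base_calls,
            n_duplicates_removed=st.n_duplicates_removed,
            n_heterozygous=st.n_heterozygous,
            n_multiallelic_sites=st.n_multiallelic_sites,
            mean_coverage=st.mean_coverage,
            het_frequencies=",".join(f"{f:.6g}"
                                     for f in st.het_frequencies),
            missing_runs=";".join(f"{a}-{b}" for a, b in st.missing_runs)))
    return pd.DataFrame(rows, columns=CALLSTATS_COLUMNS)


def write_callstats_tsv(stats: Sequence[CallStats],
                        path: Union[str, Path]) -> None:
    callstats_frame(stats).to_csv(path, sep="\t", index=False)


def read_callstats_tsv(path: Union[str, Path]) -> list[CallStats]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        freqs = [float(x) for x in str(r.het_frequencies).split(",")
                 if x not in ("", "nan")]
        runs = []
        for chunk in str(r.missing_runs).split(";"):
            if chunk:
                a, b = chunk.split("-")
                runs.append((int(a), int(b)))
        out.append(CallStats(
            gene_id=r.gene_id, species=r.species,
            total_base_calls=int(r.total_base_calls),
            n_duplicates_removed=int(r.n_duplicates_removed),
            n_heterozygous=int(r.n_heterozygous),
            het_frequencies=freqs,
            n_multiallelic_sites=int(r.n_multiallelic_sites),
            mean_coverage=float(r.mean_coverage),
            missing_runs=runs))
    return out


def read_pileup_tsv(path: Union[str, Path], gene: GeneModel,
                    species: str) -> GenePileup:
    df = pd.read_csv(path, sep="\t", dtype={"base": str})
    positions = np.sort(gene.cds_positions())
    pos_index = {int(p): i for i, p in enumerate(positions)}
    deletion = np.zeros(len(positions), dtype=bool)
    reads = df[df["indel"] == 0]
    site = np.array([pos_index[p - 1] for p in reads["pos"]], dtype=np.int64)
    for p in df.loc[df["indel"] == 1, "pos"]:
        deletion[pos_index[int(p) - 1]] = True
    return GenePileup(
        gene_id=gene.gene_id, species=species, seq_id=gene.seq_id,
        positions=positions, read_site=site,
        read_base=encode_bases(list(reads["base"])),
        read_mapq=reads["mapq"].to_numpy(np.int32),
        read_proper=reads["proper_pair"].to_numpy(bool),
        read_dup=reads["dup_group"].to_numpy(np.int64),
        deletion=deletion)
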