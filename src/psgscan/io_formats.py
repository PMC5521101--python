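"""External formats: GFF3/BED12 gene models, FASTA codon alignments,
Newick trees, UCSC wiggle tracks and TSV results tables.

Internal coordinates are 0-based half-open throughout; GFF3, BED thick
fields and wiggle output use their standard dialects (GFF3 and wiggle
are 1-based, BED stays 0-based half-open).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import genetic_code as gc
from ._phylo import IndexedTree

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# Gene models

@dataclass
class GeneModel:
    """A reference gene: ordered exon intervals (0-based half-open,
    sorted by start) on one reference sequence, with strand and phase."""

    gene_id: str
    seq_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        ex = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in ex:
            if b <= a:
                raise ValueError(f"{self.gene_id}: empty exon [{a},{b})")
        for (_, b1), (a2, _) in zip(ex, ex[1:]):
            if a2 < b1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        self.exons = ex
        if self.cds_length <= 0:
            raise ValueError(f"{self.gene_id}: empty CDS")

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def n_codons(self) -> int:
        return self.cds_length // 3

    @property
    def frame_ok(self) -> bool:
        return self.cds_length % 3 == 0

    def cds_positions(self) -> np.ndarray:
        """Reference positions of every CDS base, in transcription order
        (descending reference coordinates on the minus strand)."""
        pos = np.concatenate([np.arange(a, b) for a, b in self.exons])
        return pos[::-1].copy() if self.strand == "-" else pos

    def codon_positions(self, codon: int) -> np.ndarray:
        """The three reference positions of codon ``codon`` (transcription
        order)."""
        if not 0 <= codon < self.n_codons:
            raise IndexError(f"codon {codon} outside gene {self.gene_id}")
        return self.cds_positions()[3 * codon:3 * codon + 3]

    def exon_of_cds_index(self) -> np.ndarray:
        """Exon ordinal (transcription order) for every CDS base."""
        parts = [np.full(b - a, i) for i, (a, b) in enumerate(self.exons)]
        out = np.concatenate(parts)
        if self.strand == "-":
            out = out[::-1]
            out = len(self.exons) - 1 - out
        return out

    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


def read_gene_models(path: PathLike) -> list[GeneModel]:
    """Read CDS gene models from GFF3 or BED12 (sniffed by extension,
    '.bed' means BED12, anything else is treated as GFF3).

    Genes whose CDS length is not a multiple of 3 are retained but
    logged; downstream QC excludes them.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        models = _read_bed12(path)
    else:
        models = _read_gff3(path)
    for m in models:
        if not m.frame_ok:
            logger.warning("gene %s: CDS length %d not divisible by 3",
                           m.gene_id, m.cds_length)
    return models


def _read_gff3(path: Path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(parts)}")
            seqid, _, ftype, start, end, _, strand, phase, attrs = parts
            if ftype != "CDS":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates")
            if start_i < 1 or end_i < start_i:
                raise ParseError(f"{path}:{lineno}: invalid interval "
                                 f"{start}-{end}")
            if strand not in "+-":
                raise ParseError(f"{path}:{lineno}: strand {strand!r}")
            attr = _parse_gff_attrs(attrs, path, lineno)
            gid = attr.get("Parent") or attr.get("ID")
            if gid is None:
                raise ParseError(f"{path}:{lineno}: CDS lacks Parent/ID")
            rec = genes.setdefault(gid, dict(seq_id=seqid, strand=strand,
                                             exons=[], phase=phase))
            if gid not in order:
                order.append(gid)
            if rec["seq_id"] != seqid or rec["strand"] != strand:
                raise ParseError(f"{path}:{lineno}: gene {gid} mixes "
                                 "sequences or strands")
            rec["exons"].append((start_i - 1, end_i))  # to 0-based half-open
    models = []
    for gid in order:
        rec = genes[gid]
        phase = rec["phase"]
        models.append(GeneModel(gid, rec["seq_id"], rec["strand"],
                                rec["exons"],
                                int(phase) if phase in "012" else 0))
    return models


def _parse_gff_attrs(attrs: str, path: Path, lineno: int) -> dict:
    out = {}
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise ParseError(f"{path}:{lineno}: malformed attribute "
                             f"{chunk!r}")
        k, v = chunk.split("=", 1)
        out[k] = v
    return out


def _read_bed12(path: Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ParseError(f"{path}:{lineno}: BED12 needs 12 fields, "
                                 f"got {len(parts)}")
            chrom, start, _end, name, _score, strand = parts[:6]
            try:
                start_i = int(start)
                n_blocks = int(parts[9])
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer BED12 field")
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError(f"{path}:{lineno}: blockCount mismatch")
            exons = [(start_i + off, start_i + off + sz)
                     for off, sz in zip(offsets, sizes)]
            models.append(GeneModel(name, chrom, strand, exons))
    return models


def write_gene_models(models: Sequence[GeneModel], path: PathLike,
                      fmt: str = "gff3") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if fmt == "gff3":
            fh.write("##gff-version 3\n")
            for m in models:
                for (a, b) in m.exons:
                    fh.write("\t".join([
                        m.seq_id, "psgscan", "CDS", str(a + 1), str(b), ".",
                        m.strand, str(m.cds_phase),
                        f"ID=cds_{m.gene_id};Parent={m.gene_id}",
                    ]) + "\n")
        elif fmt == "bed12":
            for m in models:
                a0, b0 = m.span()
                sizes = ",".join(str(b - a) for a, b in m.exons)
                offs = ",".join(str(a - a0) for a, _ in m.exons)
                fh.write("\t".join([
                    m.seq_id, str(a0), str(b0), m.gene_id, "0", m.strand,
                    str(a0), str(b0), "0", str(len(m.exons)), sizes, offs,
                ]) + "\n")
        else:
            raise ValueError(f"unknown gene-model format {fmt!r}")


# ---------------------------------------------------------------------------
# Codon alignments

@dataclass
class CodonAlignment:
    """In-frame multi-species nucleotide alignment in reference
    coordinates.  Symbols: A/C/G/T, two-base IUPAC ambiguity codes,
    N (missing) and '-' (gap/deletion)."""

    gene_id: str
    taxa: list[str]
    sequences: list[str]
    #: optional reference positions per codon: (n_codons, 3) array
    coordinate_map: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"{self.gene_id}: empty alignment")
        L = len(self.sequences[0])
        if any(len(s) != L for s in self.sequences):
            raise ValueError(f"{self.gene_id}: ragged alignment")
        if L == 0 or L % 3:
            raise ValueError(f"{self.gene_id}: length {L} not a positive "
                             "multiple of 3")
        if len(self.taxa) != len(self.sequences):
            raise ValueError(f"{self.gene_id}: taxa/sequence count mismatch")
        norm = []
        for t, s in zip(self.taxa, self.sequences):
            s = s.upper().replace("U", "T")
            bad = set(s) - gc.ALLOWED_SYMBOLS
            if bad:
                raise ValueError(f"{self.gene_id}/{t}: illegal symbols "
                                 f"{sorted(bad)}")
            norm.append(s)
        self.sequences = norm
        if self.coordinate_map is not None:
            cm = np.asarray(self.coordinate_map)
            if cm.shape != (self.n_codons, 3):
                raise ValueError(f"{self.gene_id}: coordinate_map shape "
                                 f"{cm.shape} != ({self.n_codons}, 3)")
            self.coordinate_map = cm

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def sequence_of(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    def subset_codons(self, keep: np.ndarray) -> "CodonAlignment":
        """New alignment restricted to codon columns ``keep`` (bool mask
        or index array)."""
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        seqs = ["".join(s[3 * i:3 * i + 3] for i in idx)
                for s in self.sequences]
        cm = self.coordinate_map[idx] if self.coordinate_map is not None \
            else None
        return CodonAlignment(self.gene_id, list(self.taxa), seqs, cm)


def read_alignment_fasta(path: PathLike, gene_id: Optional[str] = None
                         ) -> CodonAlignment:
    """Read a codon alignment from FASTA.  Symbols are uppercased and U
    is mapped to T; anything outside the consensus alphabet is rejected."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: empty FASTA")
    taxa = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    lens = {len(s) for s in seqs}
    if len(lens) != 1:
        raise ParseError(f"{path}: ragged record lengths {sorted(lens)}")
    return CodonAlignment(gene_id or path.stem, taxa, seqs)


def write_alignment_fasta(aln: CodonAlignment, path: PathLike,
                          width: int = 60) -> None:
    recs = [SeqRecord(Seq(s), id=t, description="")
            for t, s in zip(aln.taxa, aln.sequences)]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


# ---------------------------------------------------------------------------
# Trees

def read_tree(path_or_newick: Union[PathLike, str]) -> IndexedTree:
    s = str(path_or_newick)
    if "(" not in s and Path(s).exists():
        s = Path(s).read_text()
    return IndexedTree.from_newick(s)


def write_tree(tree: IndexedTree, path: PathLike) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Wiggle tracks

WIGGLE_MAX_SCORE = 10.0  # -log10 floor corresponding to posterior 1-1e-10


def write_wiggle(pscs: Sequence[tuple], gene: GeneModel,
                 path_or_handle: Union[PathLike, TextIO],
                 track_name: Optional[str] = None) -> None:
    """Write positively selected codons as a variableStep wiggle track.

    Each PSC is a ``(codon_index, posterior, ...)`` tuple; the score is
    -log10(1 - posterior), a surrogate P-value scale for the BEB
    posterior, emitted at the codon's three reference positions
    (1-based, ascending regardless of strand).
    """
    own = not hasattr(path_or_handle, "write")
    fh = open(path_or_handle, "w") if own else path_or_handle
    try:
        name = track_name or f"PSC_{gene.gene_id}"
        fh.write(f'track type=wiggle_0 name="{name}" '
                 'description="-log10(1-BEB posterior) of positively '
                 'selected codons"\n')
        fh.write(f"variableStep chrom={gene.seq_id}\n")
        rows = []
        for psc in pscs:
            codon, posterior = psc[0], psc[1]
            if not 0 <= codon < gene.n_codons:
                raise ValueError(f"PSC codon {codon} outside gene "
                                 f"{gene.gene_id}")
            score = -math.log10(max(1.0 - posterior, 10.0 ** -WIGGLE_MAX_SCORE))
            for pos in gene.codon_positions(codon):
                rows.append((int(pos) + 1, score))
        for pos, score in sorted(rows):
            fh.write(f"{pos}\t{score:.6g}\n")
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# Results tables

@dataclass
class ResultRecord:
    """One gene's sites-test outcome."""

    gene_id: str
    n_codons_analyzed: int
    lnL_m7: float
    lnL_m8: float
    LRT: float
    p_empirical: float
    q_value: float
    dN: float
    dS: float
    dN_dS: float
    psg_flag: bool
    #: list of (codon index, BEB posterior, genomic start, genomic end)
    psc_list: list[tuple[int, float, int, int]] = field(default_factory=list)


RESULT_COLUMNS = ["gene_id", "n_codons_analyzed", "lnL_m7", "lnL_m8", "LRT",
                  "p_empirical", "q_value", "dN", "dS", "dN_dS", "psg_flag",
                  "psc_list"]
RESULTS_VERSION = "psgscan_results_v1"


def _fmt_float(x: float) -> str:
    return f"{x:.6g}"


def _fmt_pscs(pscs) -> str:
    return ";".join(f"{c}|{p:.6g}|{a}|{b}" for c, p, a, b in pscs)


def _parse_pscs(s: str) -> list[tuple[int, float, int, int]]:
    if not s or s != s:  # empty or NaN
        return []
    out = []
    for chunk in str(s).split(";"):
        c, p, a, b = chunk.split("|")
        out.append((int(c), float(p), int(a), int(b)))
    return out


def write_results_tsv(records: Sequence[ResultRecord],
                      path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {RESULTS_VERSION}\n")
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in records:
            fh.write("\t".join([
                r.gene_id, str(r.n_codons_analyzed),
                _fmt_float(r.lnL_m7), _fmt_float(r.lnL_m8),
                _fmt_float(r.LRT), _fmt_float(r.p_empirical),
                _fmt_float(r.q_value), _fmt_float(r.dN), _fmt_float(r.dS),
                _fmt_float(r.dN_dS), str(int(r.psg_flag)),
                _fmt_pscs(r.psc_list),
            ]) + "\n")


def read_results_tsv(path: PathLike) -> list[ResultRecord]:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"gene_id": str}, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        out.append(ResultRecord(
            gene_id=row.gene_id,
            n_codons_analyzed=int(row.n_codons_analyzed),
            lnL_m7=float(row.lnL_m7), lnL_m8=float(row.lnL_m8),
            LRT=float(row.LRT), p_empirical=float(row.p_empirical),
            q_value=float(row.q_value), dN=float(row.dN), dS=float(row.dS),
            dN_dS=float(row.dN_dS), psg_flag=bool(int(row.psg_flag)),
            psc_list=_parse_pscs(row.psc_list)))
    return out
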