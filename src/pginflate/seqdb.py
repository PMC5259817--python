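"""Construction and characterization of protein databases for proteogenomic search.

This module builds every database flavour used when evaluating the effect of
database inflation on peptide identification:

* reference protein databases read from FASTA (or generated synthetically),
* peptide-level decoy databases (pseudo-reversed / pseudo-shuffled, i.e. the
  C-terminal residue of each tryptic segment is kept in place so decoys stay
  tryptic and preserve length and amino-acid composition),
* simulated proteogenomic target databases ``1TnD`` (the reference plus an
  ``n``-fold block of simulated-novel sequence: one pseudo-reversed copy and
  ``n - 1`` pseudo-shuffled copies) and their matched ``(n+1)``-fold shuffled
  decoys,
* six-frame translations of genomic sequence (ATG to first in-frame stop),
* in-silico tryptic digestion and database statistics (total length, peptide
  counts, redundancy).

Database sizes are measured in total amino acids (AA); search-space sizes in
unique fully-tryptic peptides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

# 20 canonical residues plus X for indeterminate positions.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NT_ALPHABET = frozenset("ACGTN")

# Rare ambiguity/non-standard codes mapped to X on input.
_NONSTANDARD_AA = str.maketrans({c: "X" for c in "BJOUZ"})

Provenance = Literal["reference", "simulated_novel", "six_frame", "decoy"]

_K, _R, _P = (ord(c) for c in "KRP")

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class FastaError(ValueError):
    """Raised for malformed or empty FASTA input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One database entry: an identifier, a sequence and its provenance."""

    identifier: str
    sequence: str
    provenance: Provenance = "reference"
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.identifier!r}")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.identifier!r} contains disallowed symbols {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceDatabase:
    """An ordered collection of :class:`ProteinRecord` with a human label."""

    records: list[ProteinRecord]
    label: str = ""

    def __post_init__(self) -> None:
        ids = [r.identifier for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dups = sorted({i for i in ids if i in seen or seen.add(i)})
            raise ValueError(f"duplicate record identifiers: {dups[:10]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def total_aa(self) -> int:
        """Total length in amino acids, the conventional database-size measure."""
        return sum(len(r) for r in self.records)


@dataclass(frozen=True)
class DigestParams:
    """Trypsin digestion rule: cleave C-terminal to K/R except before P."""

    max_missed_cleavages: int = 2
    min_length: int = 8
    specificity: Literal["full", "semi"] = "full"

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not 0 <= self.max_missed_cleavages <= 10:
            raise ValueError("max_missed_cleavages must be in [0, 10]")
        if self.specificity not in ("full", "semi"):
            raise ValueError(f"unknown specificity {self.specificity!r}")


@dataclass(frozen=True)
class PeptideEntry:
    """One digested peptide with termini and missed-cleavage bookkeeping."""

    sequence: str
    missed_cleavages: int
    n_term_tryptic: bool
    c_term_tryptic: bool
    parent_id: str


@dataclass(frozen=True)
class DbStats:
    """Summary counts for a database under a digestion rule."""

    label: str
    total_aa: int
    n_proteins: int
    n_total_peptides: int
    n_unique_peptides: int

    @property
    def redundancy_proportion(self) -> float:
        """1 - unique/total: the fraction of redundant digested peptides."""
        if self.n_total_peptides == 0:
            return 0.0
        return 1.0 - self.n_unique_peptides / self.n_total_peptides


# ---------------------------------------------------------------------------
# FASTA input / output
# ---------------------------------------------------------------------------


def read_fasta(path, provenance: Provenance = "reference", label: str = "") -> SequenceDatabase:
    """Read a FASTA file into a :class:`SequenceDatabase`.

    Sequences are upper-cased; ``*`` characters (stop markers) are stripped
    with a warning, and rare non-standard residue codes (B, J, O, U, Z) are
    mapped to ``X``. Raises :class:`FastaError` for an empty file, a file
    whose first non-blank line is not a header, or duplicate identifiers.
    """
    path = str(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaError(
                        f"{path}: line {lineno}: expected a FASTA header "
                        f"starting with '>', got {line.strip()[:40]!r}"
                    )
                break
        else:
            raise FastaError(f"{path}: empty FASTA file")

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    n_stars = 0
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate FASTA identifier {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        stars = seq.count("*")
        if stars:
            n_stars += stars
            seq = seq.replace("*", "")
        seq = seq.translate(_NONSTANDARD_AA)
        tags = _parse_header_tags(rec.description)
        records.append(
            ProteinRecord(
                identifier=rec.id,
                sequence=seq,
                provenance=tags.get("provenance", provenance),  # type: ignore[arg-type]
                source_tag=tags.get("source_tag", ""),
            )
        )
    if n_stars:
        logger.warning("%s: stripped %d '*' characters", path, n_stars)
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return SequenceDatabase(records, label=label or path)


def _parse_header_tags(description: str) -> dict[str, str]:
    tags: dict[str, str] = {}
    for token in description.split()[1:]:
        if "=" in token:
            key, value = token.split("=", 1)
            tags[key] = value
    return tags


def write_fasta(db: SequenceDatabase, path, width: int = 60) -> None:
    """Write a database to FASTA, 60-column wrapped, with provenance tags."""
    records = []
    for rec in db:
        desc = f"provenance={rec.provenance}"
        if rec.source_tag:
            desc += f" source_tag={rec.source_tag}"
        records.append(SeqRecord(Seq(rec.sequence), id=rec.identifier, description=desc))
    with open(str(path), "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Tryptic digestion
# ---------------------------------------------------------------------------


def cleavage_sites(sequence: str) -> list[int]:
    """Positions ``p`` (0 < p < L) where trypsin cleaves between p-1 and p."""
    return [
        p
        for p in range(1, len(sequence))
        if sequence[p - 1] in "KR" and sequence[p] != "P"
    ]


def digest(record: ProteinRecord, params: DigestParams) -> list[PeptideEntry]:
    """In-silico tryptic digestion of one protein.

    ``full`` specificity returns every peptide delimited by cleavage points
    (protein termini count as tryptic) spanning at most
    ``max_missed_cleavages`` internal cleavage points; ``semi`` additionally
    returns peptides with exactly one tryptic terminus.
    """
    seq = record.sequence
    L = len(seq)
    sites = cleavage_sites(seq)
    bounds = [0] + sites + [L]
    mc = params.max_missed_cleavages
    out: list[PeptideEntry] = []

    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + mc + 2, len(bounds))):
            s, e = bounds[i], bounds[j]
            if e - s >= params.min_length:
                out.append(PeptideEntry(seq[s:e], j - i - 1, True, True, record.identifier))

    if params.specificity == "semi":
        site_set = set(sites)
        # Tryptic N-terminus, ragged C-terminus.
        for i in range(len(bounds) - 1):
            s = bounds[i]
            e_cap = bounds[min(i + mc + 1, len(bounds) - 1)]
            for e in range(s + params.min_length, e_cap + 1):
                if e == L or e in site_set:
                    continue  # both termini tryptic: already emitted above
                n_internal = sum(1 for p in sites if s < p < e)
                if n_internal <= mc:
                    out.append(PeptideEntry(seq[s:e], n_internal, True, False, record.identifier))
        # Tryptic C-terminus, ragged N-terminus.
        for j in range(1, len(bounds)):
            e = bounds[j]
            s_cap = bounds[max(j - mc - 1, 0)]
            for s in range(s_cap, e - params.min_length + 1):
                if s == 0 or s in site_set:
                    continue
                n_internal = sum(1 for p in sites if s < p < e)
                if n_internal <= mc:
                    out.append(PeptideEntry(seq[s:e], n_internal, False, True, record.identifier))

    return out


def db_stats(db: SequenceDatabase, params: DigestParams | None = None) -> DbStats:
    """Protein, length and digested-peptide counts for a database.

    Peptides containing ``X`` are excluded from the peptide statistics:
    indeterminate residues cannot be matched by a search engine.
    """
    params = params or DigestParams()
    n_total = 0
    unique: set[str] = set()
    for rec in db:
        for pep in digest(rec, params):
            if "X" in pep.sequence:
                continue
            n_total += 1
            unique.add(pep.sequence)
    return DbStats(
        label=db.label,
        total_aa=db.total_aa,
        n_proteins=len(db),
        n_total_peptides=n_total,
        n_unique_peptides=len(unique),
    )


# ---------------------------------------------------------------------------
# Peptide-level decoy transforms
# ---------------------------------------------------------------------------


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def pseudo_reverse(peptide: str) -> str:
    """Reverse a peptide keeping its C-terminal residue in place."""
    if not peptide:
        raise ValueError("empty peptide")
    return peptide[-2::-1] + peptide[-1]


def pseudo_shuffle(peptide: str, rng) -> str:
    """Uniformly permute all residues of a peptide except the C-terminal one."""
    if not peptide:
        raise ValueError("empty peptide")
    rng = _as_rng(rng)
    order = rng.permutation(len(peptide) - 1)
    return "".join(peptide[i] for i in order) + peptide[-1]


# -- whole-database transforms, vectorized over a flat residue array --------


def _concat_codes(db: SequenceDatabase) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten a database to a uint8 array plus protein starts and lengths."""
    lengths = np.fromiter((len(r) for r in db), dtype=np.int64, count=len(db))
    blob = "".join(r.sequence for r in db)
    codes = np.frombuffer(blob.encode("ascii"), dtype=np.uint8).copy()
    starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
    return codes, starts, lengths


def _segment_starts(codes: np.ndarray, protein_starts: np.ndarray) -> np.ndarray:
    """Start indices of mc=0 tryptic segments over the flat array.

    A segment begins at each protein start and after every K/R not followed
    by P (protein boundaries never merge).
    """
    begin = np.zeros(codes.size, dtype=bool)
    begin[protein_starts] = True
    kr = (codes == _K) | (codes == _R)
    internal = np.zeros(codes.size, dtype=bool)
    internal[1:] = kr[:-1] & (codes[1:] != _P)
    internal[protein_starts] = False
    return np.flatnonzero(begin | internal)


def _transform_codes(codes: np.ndarray, seg_starts: np.ndarray, method: str,
                     rng: np.random.Generator | None) -> np.ndarray:
    """Apply pseudo-reverse or pseudo-shuffle within each segment.

    The last residue of every segment is fixed; the interior is reversed or
    uniformly permuted. Pure index arithmetic, so it scales to databases of
    hundreds of millions of residues.
    """
    n = codes.size
    seg_ends = np.append(seg_starts[1:], n)
    seg_lens = seg_ends - seg_starts
    pos = np.arange(n, dtype=np.int64)
    start_of = np.repeat(seg_starts, seg_lens)
    end_of = np.repeat(seg_ends, seg_lens)
    interior = pos < end_of - 1
    out = codes.copy()
    if method == "pseudo_reverse":
        src = start_of + end_of - 2 - pos
        out[interior] = codes[src[interior]]
    elif method == "pseudo_shuffle":
        if rng is None:
            raise ValueError("pseudo_shuffle requires an rng")
        seg_of = np.repeat(np.arange(seg_starts.size, dtype=np.int64), seg_lens)
        ii = np.flatnonzero(interior)
        # Interior positions are already grouped by segment in ascending
        # order, so one sort of (segment << 32 | random 32-bit key) yields an
        # independent uniform permutation within every segment.
        key = (seg_of[ii] << np.int64(32)) | rng.integers(
            0, 2**32, size=ii.size, dtype=np.uint32
        ).astype(np.int64)
        order = np.argsort(key, kind="stable")
        out[ii] = codes[ii[order]]
    else:
        raise ValueError(f"unknown decoy method {method!r}")
    return out


def _transform_database(db: SequenceDatabase, method: str, rng,
                        id_suffix: str, provenance: Provenance,
                        source_tag: str, _flat=None) -> list[ProteinRecord]:
    if _flat is None:
        codes, starts, lengths = _concat_codes(db)
        seg_starts = _segment_starts(codes, starts)
    else:
        codes, starts, lengths, seg_starts = _flat
    out = _transform_codes(codes, seg_starts, method, _as_rng(rng) if rng is not None else None)
    blob = out.tobytes().decode("ascii")
    records = []
    for rec, s, ln in zip(db, starts, lengths):
        records.append(
            ProteinRecord(
                identifier=f"{rec.identifier}{id_suffix}",
                sequence=blob[s : s + ln],
                provenance=provenance,
                source_tag=source_tag,
            )
        )
    return records


def _flatten(db: SequenceDatabase):
    codes, starts, lengths = _concat_codes(db)
    return codes, starts, lengths, _segment_starts(codes, starts)


def make_decoy_db(db: SequenceDatabase,
                  method: Literal["pseudo_reverse", "pseudo_shuffle"] = "pseudo_reverse",
                  rng=None) -> SequenceDatabase:
    """Build a same-size decoy database, one decoy record per target record.

    Each protein is segmented at every tryptic cleavage point (mc=0
    segments); each segment is individually pseudo-reversed or
    pseudo-shuffled and the segments are re-concatenated in order, so the
    decoy protein has the target's exact length and residue composition.
    """
    records = _transform_database(
        db, method, rng, id_suffix="|decoy", provenance="decoy", source_tag=method
    )
    return SequenceDatabase(records, label=f"{db.label}|decoy[{method}]")


def build_simulated_target(db: SequenceDatabase, n: int, seed: int = 0) -> SequenceDatabase:
    """Build the simulated proteogenomic target database ``1TnD``.

    The output is the reference database followed by an ``n``-fold block of
    simulated-novel sequence: one pseudo-reversed copy of the reference and
    ``n - 1`` independently pseudo-shuffled copies. Total length is exactly
    ``(n + 1)`` times the reference length.
    """
    if n < 0:
        raise ValueError("inflation factor n must be >= 0")
    records = list(db.records)
    flat = _flatten(db) if n > 0 else None
    for k in range(n):
        if k == 0:
            method, tag = "pseudo_reverse", "rev1"
            rng = None
        else:
            method, tag = "pseudo_shuffle", f"shuf{k}"
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0, k)))
        records.extend(
            _transform_database(
                db, method, rng, id_suffix=f"|sim_{tag}",
                provenance="simulated_novel", source_tag=tag, _flat=flat,
            )
        )
    return SequenceDatabase(records, label=f"1T{n}D[{db.label}]")


def build_simulated_decoy(db: SequenceDatabase, n: int, seed: int = 0) -> SequenceDatabase:
    """Build the ``(n+1)D`` decoy database matched to ``1TnD``.

    ``n + 1`` independently pseudo-shuffled copies of the reference, drawn
    from random streams disjoint from those used for the target copies.
    """
    if n < 0:
        raise ValueError("inflation factor n must be >= 0")
    records: list[ProteinRecord] = []
    flat = _flatten(db)
    for k in range(n + 1):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, k)))
        records.extend(
            _transform_database(
                db, "pseudo_shuffle", rng, id_suffix=f"|decoy_shuf{k}",
                provenance="decoy", source_tag=f"decoy_shuf{k}", _flat=flat,
            )
        )
    return SequenceDatabase(records, label=f"{n + 1}D[{db.label}]")


# ---------------------------------------------------------------------------
# Six-frame translation
# ---------------------------------------------------------------------------

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_TABLE.stop_codons)
_FORWARD = dict(_TABLE.forward_table)


def _translate_codon(codon: str) -> str:
    if codon in _STOPS:
        return "*"
    return _FORWARD.get(codon, "X")  # codons containing N translate to X


def six_frame_translate(genome: SequenceDatabase, min_orf_aa: int = 8) -> SequenceDatabase:
    """Translate a genome in all six frames into a protein database.

    For each frame an open reading frame starts at an ATG codon and ends at
    the first in-frame stop codon (stop excluded). ORFs shorter than
    ``min_orf_aa`` are dropped. A trailing region with no in-frame stop
    before the contig end is emitted and flagged ``partial``. Identifiers
    encode contig, strand, frame and 1-based inclusive coordinates on the
    forward strand. Alternative start codons are not considered.
    """
    if min_orf_aa < 1:
        raise ValueError("min_orf_aa must be >= 1")
    records: list[ProteinRecord] = []
    for rec in genome:
        seq = rec.sequence
        bad = set(seq) - NT_ALPHABET
        if bad:
            raise ValueError(
                f"record {rec.identifier!r} is not a nucleotide sequence "
                f"(A/C/G/T/N): found {sorted(bad)}"
            )
        N = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else str(Seq(seq).reverse_complement())
            for frame in range(3):
                records.extend(
                    _orfs_in_frame(s, frame, strand, N, rec.identifier, min_orf_aa)
                )
    return SequenceDatabase(records, label=f"6FT[{genome.label}]")


def _orfs_in_frame(s: str, frame: int, strand: str, contig_len: int,
                   contig: str, min_orf_aa: int) -> list[ProteinRecord]:
    records = []
    aa: list[str] = []
    orf_start: int | None = None  # 0-based position on `s`
    for i in range(frame, len(s) - 2, 3):
        codon = s[i : i + 3]
        if orf_start is None:
            if codon == "ATG":
                orf_start = i
                aa = ["M"]
            continue
        residue = _translate_codon(codon)
        if residue == "*":
            records.append(
                _orf_record(aa, orf_start, i, strand, contig_len, contig,
                            frame, partial=False, min_orf_aa=min_orf_aa)
            )
            orf_start, aa = None, []
        else:
            aa.append(residue)
    if orf_start is not None:
        end = orf_start + 3 * len(aa)
        records.append(
            _orf_record(aa, orf_start, end, strand, contig_len, contig,
                        frame, partial=True, min_orf_aa=min_orf_aa)
        )
    return [r for r in records if r is not None]


def _orf_record(aa: list[str], start: int, end: int, strand: str,
                contig_len: int, contig: str, frame: int,
                partial: bool, min_orf_aa: int) -> ProteinRecord | None:
    # `start`/`end` are 0-based [start, end) on the frame's own strand; map
    # them to 1-based inclusive coordinates on the forward strand.
    if len(aa) < min_orf_aa:
        return None
    if strand == "+":
        fwd_start, fwd_end = start + 1, end
    else:
        fwd_start, fwd_end = contig_len - end + 1, contig_len - start
    tag = f"strand={strand};frame={frame + 1}" + (";partial" if partial else "")
    ident = f"{contig}|{strand}{frame + 1}|{fwd_start}-{fwd_end}" + ("|partial" if partial else "")
    return ProteinRecord(
        identifier=ident, sequence="".join(aa), provenance="six_frame", source_tag=tag
    )


# ---------------------------------------------------------------------------
# Synthetic reference databases
# ---------------------------------------------------------------------------

# Approximate Swiss-Prot residue composition; K+R ~ 11% gives realistic
# tryptic segment lengths (mean ~ 9 AA).
_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_FREQS = np.array([
    0.0826, 0.0137, 0.0546, 0.0672, 0.0386, 0.0708, 0.0228, 0.0593, 0.0582,
    0.0965, 0.0241, 0.0406, 0.0472, 0.0394, 0.0553, 0.0660, 0.0535, 0.0687,
    0.0110, 0.0292,
])
_AA_FREQS = _AA_FREQS / _AA_FREQS.sum()


def synthetic_reference_db(total_aa: int, n_proteins: int, seed: int = 0,
                           label: str = "synthetic-reference") -> SequenceDatabase:
    """Generate a random protein database of an exact total AA length.

    Residues are drawn i.i.d. from an approximate Swiss-Prot composition;
    protein lengths vary around the mean but sum exactly to ``total_aa``.
    Used to stand in for a reference proteome when only database sizes (not
    real sequences) matter.
    """
    if total_aa < n_proteins:
        raise ValueError("total_aa must be at least n_proteins")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    avg = total_aa / n_proteins
    lengths = rng.integers(max(1, int(avg * 0.5)), int(avg * 1.5) + 2, size=n_proteins)
    lengths = np.maximum(1, (lengths * (total_aa / lengths.sum())).astype(np.int64))
    lengths[0] += total_aa - int(lengths.sum())
    if lengths[0] < 1:  # pathological rounding; rebalance from the largest
        k = int(np.argmax(lengths))
        lengths[k] += lengths[0] - 1
        lengths[0] = 1
    codes = rng.choice(
        np.frombuffer(_AA_ORDER.encode("ascii"), dtype=np.uint8),
        size=total_aa, p=_AA_FREQS,
    )
    blob = codes.tobytes().decode("ascii")
    starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
    records = [
        ProteinRecord(f"SYN{i:06d}", blob[s : s + ln])
        for i, (s, ln) in enumerate(zip(starts, lengths))
    ]
    return SequenceDatabase(records, label=label)


def stats_tsv(stats: Iterable[DbStats]) -> str:
    """Render database statistics as a TSV table with one header row."""
    header = "label\tn_proteins\ttotal_aa\tn_total_peptides\tn_unique_peptides\tredundancy_proportion"
    rows = [
        f"{s.label}\t{s.n_proteins}\t{s.total_aa}\t{s.n_total_peptides}"
        f"\t{s.n_unique_peptides}\t{s.redundancy_proportion:.6f}"
        for s in stats
    ]
    return "\n".join([header, *rows]) + "\n"
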