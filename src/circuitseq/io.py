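"""Readers and containers for circuit annotations, fragment alignments and
strand-specific transcription profiles.

All internal coordinates are 0-based half-open.  GFF3 (1-based inclusive)
and SAM (1-based) are converted at the boundary and never leak inward.
A "fragment" is the template-level unit of a paired-end library: one
properly paired read pair becomes one interval spanning the insert.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

__all__ = [
    "PartType",
    "Part",
    "CircuitAnnotation",
    "FragmentAlignment",
    "TranscriptionProfile",
    "FragmentLengthDistribution",
    "GeneCountTable",
    "load_annotation",
    "load_references",
    "load_fragments",
    "fragments_from_sam",
    "build_strand_profiles",
    "fragment_length_distribution",
    "count_gene_fragments",
    "write_bedgraph",
    "read_bedgraph",
    "write_fragments_bed",
]

SENSE = "sense"
ANTISENSE = "antisense"

# SAM flag pairs for a reverse-stranded (dUTP/RNAtag-seq style) library:
# 83/163 -> fragment originates from the sense strand, 99/147 -> antisense.
_SENSE_FLAGS = frozenset({83, 163})
_ANTISENSE_FLAGS = frozenset({99, 147})


class PartType(str, Enum):
    PROMOTER = "promoter"
    RIBOZYME = "ribozyme"
    RBS = "rbs"
    CDS = "cds"
    TERMINATOR = "terminator"
    SCAR = "scar"
    OTHER = "other"


# GFF "type" column aliases accepted on input.
_TYPE_ALIASES = {
    "promoter": PartType.PROMOTER,
    "ribozyme": PartType.RIBOZYME,
    "rbs": PartType.RBS,
    "ribosome_entry_site": PartType.RBS,
    "cds": PartType.CDS,
    "gene": PartType.CDS,
    "terminator": PartType.TERMINATOR,
    "scar": PartType.SCAR,
    "other": PartType.OTHER,
    "misc_feature": PartType.OTHER,
}

# Attributes holding absolute 1-based GFF coordinates, converted on load.
_COORD_ATTRIBUTES = ("cut_site", "tss")


@dataclass(frozen=True)
class Part:
    """A typed genetic part on a reference, 0-based half-open coordinates."""

    name: str
    part_type: PartType
    reference_id: str
    start: int
    end: int
    strand: str = "+"
    attributes: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"part {self.name}: start must be < end "
                             f"({self.start} >= {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"part {self.name}: strand must be + or -")
        cut = self.attributes.get("cut_site")
        if cut is not None and not (self.start <= int(cut) < self.end):
            raise ValueError(
                f"part {self.name}: cut_site {cut} outside [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def cut_site(self) -> int | None:
        cut = self.attributes.get("cut_site")
        return None if cut is None else int(cut)

    @property
    def tss(self) -> int | None:
        """Transcription start site; defaults to the part end (first
        transcribed base just downstream of a promoter part)."""
        tss = self.attributes.get("tss")
        if tss is not None:
            return int(tss)
        if self.part_type is PartType.PROMOTER:
            return self.end if self.strand == "+" else self.start - 1
        return None


@dataclass
class CircuitAnnotation:
    """Ordered (5'->3' on the sense strand) list of parts on one reference."""

    parts: list[Part]
    reference_id: str
    reference_length: int

    def __post_init__(self) -> None:
        self.parts = sorted(self.parts, key=lambda p: (p.start, p.end))
        for part in self.parts:
            if part.end > self.reference_length:
                raise ValueError(
                    f"part {part.name} extends past reference end "
                    f"({part.end} > {self.reference_length})")
        self._check_no_same_type_overlap()

    def _check_no_same_type_overlap(self) -> None:
        by_key: dict[tuple[PartType, str], list[Part]] = {}
        for part in self.parts:
            by_key.setdefault((part.part_type, part.strand), []).append(part)
        for (ptype, strand), group in by_key.items():
            for a, b in zip(group, group[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping {ptype.value} parts on strand {strand}: "
                        f"{a.name} and {b.name}")

    def of_type(self, part_type: PartType) -> list[Part]:
        return [p for p in self.parts if p.part_type is part_type]

    def __iter__(self):
        return iter(self.parts)

    def __len__(self) -> int:
        return len(self.parts)


@dataclass(frozen=True)
class FragmentAlignment:
    """One sequenced template fragment mapped to a reference."""

    reference_id: str
    start: int
    end: int
    strand_class: str
    mapq: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"fragment end {self.end} <= start {self.start}")
        if self.strand_class not in (SENSE, ANTISENSE):
            raise ValueError(f"unknown strand class {self.strand_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptionProfile:
    """Per-nucleotide transcript abundance M(x) on one strand.

    Raw profiles are in fragment-count units; normalized/calibrated profiles
    are in au.  Values are non-negative and the array length equals the
    reference length.
    """

    reference_id: str
    strand_class: str
    values: np.ndarray
    sample_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile values must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("profile values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    def mean_over(self, start: int, end: int) -> float:
        """Arithmetic mean of the profile over [start, end)."""
        if not (0 <= start < end <= len(self.values)):
            raise ValueError(f"window [{start}, {end}) outside profile bounds "
                             f"[0, {len(self.values)})")
        return float(self.values[start:end].mean())

    def scaled(self, factor: float) -> "TranscriptionProfile":
        return TranscriptionProfile(self.reference_id, self.strand_class,
                                    self.values * factor, self.sample_id)


@dataclass
class FragmentLengthDistribution:
    """Empirical distribution of template fragment lengths."""

    lengths: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=int)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.lengths) != len(self.probabilities):
            raise ValueError("lengths and probabilities differ in size")
        if np.any(self.lengths < 1):
            raise ValueError("fragment lengths must be >= 1")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be non-negative")
        total = self.probabilities.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, expected 1")

    @property
    def mean(self) -> float:
        return float(np.dot(self.lengths, self.probabilities))

    @property
    def max_length(self) -> int:
        return int(self.lengths.max())

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.lengths, size=size, p=self.probabilities)

    @classmethod
    def point_mass(cls, length: int) -> "FragmentLengthDistribution":
        return cls(np.array([length]), np.array([1.0]))


@dataclass
class GeneCountTable:
    """Gene x sample fragment counts plus the metadata FPKM needs."""

    counts: pd.DataFrame              # genes x samples, integer
    gene_lengths: pd.Series           # nt per gene
    total_fragments: pd.Series        # mapped fragments per sample

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.index) - set(self.gene_lengths.index)
        if missing:
            raise ValueError(f"missing gene lengths for {sorted(missing)}")
        for sample in self.counts.columns:
            if self.total_fragments[sample] < self.counts[sample].sum():
                raise ValueError(
                    f"sample {sample}: total mapped fragments below the "
                    "annotated-gene column sum")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Annotation loading


def load_annotation(gff_path: str | Path,
                    reference_length: int | None = None) -> CircuitAnnotation:
    """Parse a GFF3 part annotation into a :class:`CircuitAnnotation`.

    GFF 1-based inclusive coordinates become 0-based half-open.  The part
    type comes from the GFF "type" column, overridable with a ``part_type``
    attribute.  ``cut_site``/``tss`` attributes are absolute 1-based GFF
    coordinates and are converted with the same shift.  Reference length is
    taken from a ``##sequence-region`` pragma unless given explicitly.
    """
    gff_path = Path(gff_path)
    parts: list[Part] = []
    reference_id: str | None = None
    pragma_length: int | None = None
    with open(gff_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("##sequence-region"):
                tokens = line.split()
                if len(tokens) >= 4:
                    pragma_length = int(tokens[3])
                continue
            if line.startswith("#"):
                continue
            feature = feature_from_line(line)
            type_key = feature.featuretype.lower()
            attrs = {k: v[0] for k, v in feature.attributes.items() if v}
            type_key = str(attrs.get("part_type", type_key)).lower()
            if type_key not in _TYPE_ALIASES:
                raise ValueError(
                    f"{gff_path.name}:{lineno}: unknown part type "
                    f"{feature.featuretype!r} in line {line!r}")
            part_type = _TYPE_ALIASES[type_key]
            attributes: dict[str, object] = {}
            for key, value in attrs.items():
                if key in ("Name", "ID", "part_type"):
                    continue
                if key in _COORD_ATTRIBUTES:
                    attributes[key] = int(value) - 1   # 1-based -> 0-based
                else:
                    attributes[key] = value
            name = attrs.get("Name", attrs.get("ID", f"part_{lineno}"))
            parts.append(Part(
                name=str(name),
                part_type=part_type,
                reference_id=feature.seqid,
                start=feature.start - 1,
                end=feature.end,
                strand=feature.strand if feature.strand in "+-" else "+",
                attributes=attributes,
            ))
            if reference_id is None:
                reference_id = feature.seqid
            elif feature.seqid != reference_id:
                raise ValueError(
                    f"{gff_path.name}:{lineno}: multiple reference ids "
                    f"({reference_id!r} and {feature.seqid!r})")
    if not parts:
        raise ValueError(f"{gff_path}: no features found")
    if reference_length is None:
        reference_length = pragma_length
    if reference_length is None:
        reference_length = max(p.end for p in parts)
    return CircuitAnnotation(parts=parts, reference_id=reference_id,
                             reference_length=reference_length)


def load_references(fasta_path: str | Path) -> dict[str, int]:
    """Reference id -> sequence length from a (multi-)FASTA file."""
    from Bio import SeqIO

    lengths = {rec.id: len(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not lengths:
        raise ValueError(f"{fasta_path}: no sequences found")
    return lengths


# ---------------------------------------------------------------------------
# Fragment loading


def load_fragments(path_or_records,
                   library_orientation: str = "reverse",
                   ) -> list[FragmentAlignment]:
    """Load template fragments from a BED6 table or an iterable of records.

    ``library_orientation`` maps the BED strand column to a strand class:
    with a reverse-stranded library (the default; dUTP/RNAtag-seq chemistry)
    a ``+`` BED strand means the fragment came from the sense strand of the
    annotated genes; ``forward`` inverts nothing.
    Both conventions place '+' -> sense here because fragments are stored as
    template intervals whose BED strand already encodes the transcript
    strand; the orientation flag controls interpretation of raw SAM flags
    and is accepted here for symmetric configuration.
    """
    if library_orientation not in ("forward", "reverse"):
        raise ValueError("library_orientation must be 'forward' or 'reverse'")
    if isinstance(path_or_records, (str, Path)):
        table = pd.read_csv(
            path_or_records, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str, "start": int, "end": int},
        )
        records = table.itertuples(index=False)
        fragments = []
        dropped = 0
        for rec in records:
            if rec.end <= rec.start:
                dropped += 1
                continue
            strand_class = SENSE if rec.strand == "+" else ANTISENSE
            score = rec.score
            mapq = None
            try:
                mapq = int(score)
            except (TypeError, ValueError):
                mapq = None
            fragments.append(FragmentAlignment(
                reference_id=rec.chrom, start=int(rec.start), end=int(rec.end),
                strand_class=strand_class, mapq=mapq))
        if dropped:
            warnings.warn(f"dropped {dropped} fragments with end <= start")
        return fragments
    return _fragments_from_flagged_records(path_or_records)


def _fragments_from_flagged_records(records: Iterable) -> list[FragmentAlignment]:
    """Records are (reference_id, start, end, flag[, mapq]) tuples carrying
    the SAM flag of the first-in-pair read."""
    fragments = []
    skipped = 0
    dropped = 0
    for rec in records:
        reference_id, start, end, flag = rec[:4]
        mapq = rec[4] if len(rec) > 4 else None
        if flag in _SENSE_FLAGS:
            strand_class = SENSE
        elif flag in _ANTISENSE_FLAGS:
            strand_class = ANTISENSE
        else:
            skipped += 1
            continue
        if end <= start:
            dropped += 1
            continue
        fragments.append(FragmentAlignment(reference_id, int(start), int(end),
                                           strand_class, mapq))
    if skipped or dropped:
        warnings.warn(f"skipped {skipped} records with unknown flags, "
                      f"dropped {dropped} with end <= start")
    return fragments


def fragments_from_sam(path: str | Path,
                       reference_id: str | None = None,
                       ) -> list[FragmentAlignment]:
    """Adapter: properly paired primary alignments in a SAM/BAM file become
    template-level fragments.

    Only the first-in-pair mate of each proper pair is consumed; the
    fragment spans the template (insert).  Flag pairs {83,163} map to sense
    and {99,147} to antisense (reverse-stranded library).  Single-end reads
    are treated as fragments of read length, with a warning.
    """
    import pysam

    fragments: list[FragmentAlignment] = []
    skipped = 0
    single_end = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as handle:
        for read in handle:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if reference_id is not None and read.reference_name != reference_id:
                continue
            if not read.is_paired:
                single_end += 1
                strand_class = ANTISENSE if read.is_reverse else SENSE
                fragments.append(FragmentAlignment(
                    read.reference_name, read.reference_start,
                    read.reference_end, strand_class, read.mapping_quality))
                continue
            if not read.is_proper_pair:
                skipped += 1
                continue
            if not read.is_read1:
                continue  # pair is handled via read1
            flag = read.flag & 0xFF
            if flag in _SENSE_FLAGS:
                strand_class = SENSE
            elif flag in _ANTISENSE_FLAGS:
                strand_class = ANTISENSE
            else:
                skipped += 1
                continue
            start = min(read.reference_start, read.next_reference_start)
            end = start + abs(read.template_length)
            if end <= start:
                skipped += 1
                continue
            fragments.append(FragmentAlignment(
                read.reference_name, start, end, strand_class,
                read.mapping_quality))
    if single_end:
        warnings.warn(f"treated {single_end} single-end reads as fragments "
                      "of read length")
    if skipped:
        warnings.warn(f"skipped {skipped} non-proper or unrecognized records")
    return fragments


# ---------------------------------------------------------------------------
# Profiles and counting


def build_strand_profiles(fragments: Sequence[FragmentAlignment],
                          reference_length: int,
                          reference_id: str | None = None,
                          sample_id: str | None = None,
                          ) -> tuple[TranscriptionProfile, TranscriptionProfile]:
    """Pile up fragments into (sense, antisense) coverage profiles.

    The value at x is the number of fragments of that strand class with
    start <= x < end.  Units are raw fragment counts.
    """
    tracks = {SENSE: np.zeros(reference_length + 1),
              ANTISENSE: np.zeros(reference_length + 1)}
    for frag in fragments:
        if reference_id is not None and frag.reference_id != reference_id:
            continue
        if frag.start < 0 or frag.end > reference_length:
            raise ValueError(
                f"fragment [{frag.start}, {frag.end}) exceeds reference "
                f"bounds [0, {reference_length})")
        diff = tracks[frag.strand_class]
        diff[frag.start] += 1
        diff[frag.end] -= 1
    ref = reference_id
    if ref is None:
        ref = fragments[0].reference_id if fragments else "unknown"
    sense = TranscriptionProfile(ref, SENSE, np.cumsum(tracks[SENSE][:-1]),
                                 sample_id)
    antisense = TranscriptionProfile(ref, ANTISENSE,
                                     np.cumsum(tracks[ANTISENSE][:-1]),
                                     sample_id)
    return sense, antisense


def fragment_length_distribution(fragments: Sequence[FragmentAlignment],
                                 ) -> FragmentLengthDistribution:
    """Normalized empirical histogram of fragment template lengths."""
    if len(fragments) == 0:
        raise ValueError("cannot estimate a length distribution from zero fragments")
    lengths = np.array([f.length for f in fragments])
    values, counts = np.unique(lengths, return_counts=True)
    return FragmentLengthDistribution(values, counts / counts.sum())


def count_gene_fragments(fragments_by_sample: Mapping[str, Sequence[FragmentAlignment]]
                                              | Sequence[FragmentAlignment],
                         gene_annotation: Sequence[Part],
                         min_mapq: int = 10,
                         totals: Mapping[str, int] | None = None,
                         ) -> GeneCountTable:
    """Union-mode gene counting, strand-aware.

    A fragment overlapping exactly one gene on its matching strand
    increments that gene; a fragment overlapping two or more genes is
    ambiguous and counted for none.  Fragments with a mapping quality below
    ``min_mapq`` (when present) are excluded.  ``totals`` supplies
    per-sample total mapped fragment counts (library sizes); by default the
    number of input fragments per sample is used.
    """
    if not isinstance(fragments_by_sample, Mapping):
        fragments_by_sample = {"sample": fragments_by_sample}
    genes = list(gene_annotation)
    gene_names = [g.name for g in genes]
    counts = pd.DataFrame(0, index=gene_names,
                          columns=list(fragments_by_sample), dtype=int)
    for sample, fragments in fragments_by_sample.items():
        for frag in fragments:
            if frag.mapq is not None and frag.mapq < min_mapq:
                continue
            hits = [g.name for g in genes
                    if _fragment_matches_gene(frag, g)]
            if len(hits) == 1:
                counts.loc[hits[0], sample] += 1
    lengths = pd.Series({g.name: g.length for g in genes})
    if totals is None:
        totals = {s: len(f) for s, f in fragments_by_sample.items()}
    total_series = pd.Series(totals, dtype=float)
    return GeneCountTable(counts=counts, gene_lengths=lengths,
                          total_fragments=total_series)


def _fragment_matches_gene(frag: FragmentAlignment, gene: Part) -> bool:
    strand_ok = ((frag.strand_class == SENSE and gene.strand == "+")
                 or (frag.strand_class == ANTISENSE and gene.strand == "-"))
    if not strand_ok or frag.reference_id != gene.reference_id:
        return False
    return frag.start < gene.end and frag.end > gene.start


# ---------------------------------------------------------------------------
# bedGraph round trip


def write_bedgraph(profile: TranscriptionProfile, path: str | Path) -> None:
    """Write a profile as bedGraph, merging runs of equal values.

    Values are written with :func:`repr` so a round trip is bit-exact.
    """
    values = profile.values
    with open(path, "w") as out:
        out.write(f'track type=bedGraph name="{profile.sample_id or "profile"}'
                  f'.{profile.strand_class}"\n')
        if len(values) == 0:
            return
        boundaries = np.flatnonzero(np.diff(values)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(values)]))
        for start, end in zip(starts, ends):
            out.write(f"{profile.reference_id}\t{start}\t{end}\t"
                      f"{float(values[start])!r}\n")


def read_bedgraph(path: str | Path, reference_length: int,
                  strand_class: str = SENSE,
                  sample_id: str | None = None) -> TranscriptionProfile:
    values = np.zeros(reference_length)
    reference_id = "unknown"
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end, value = line.split("\t")
            values[int(start):int(end)] = float(value)
            reference_id = chrom
    return TranscriptionProfile(reference_id, strand_class, values, sample_id)


def write_fragments_bed(fragments: Sequence[FragmentAlignment],
                        path: str | Path) -> None:
    """BED6 output; strand encodes strand class (+ = sense)."""
    with open(path, "w") as out:
        for i, frag in enumerate(fragments):
            strand = "+" if frag.strand_class == SENSE else "-"
            mapq = frag.mapq if frag.mapq is not None else 255
            out.write(f"{frag.reference_id}\t{frag.start}\t{frag.end}\t"
                      f"f{i}\t{mapq}\t{strand}\n")
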