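"""Alignment, annotation, mask and lineage-table I/O, and partition building.

The in-memory model is a :class:`GenomeAlignment` whose columns carry a
``column_map`` back to original (pre-masking) 1-based coordinates, so that
feature annotations expressed in original coordinates stay resolvable after
columns have been excluded.  Partition extraction implements the two
mitogenome-specific rules this pipeline needs: minus-strand CDSs (ND6) are
reverse-complemented so their reading frame runs 5'->3', and CDSs that
overlap (ND5/ND6) are extracted per gene, duplicating the shared columns, so
the concatenated CDS alignment is the sum of gene lengths rather than their
union.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_CHARS = frozenset("ACGTNRYSWKMBDHV-")
USABLE_BASES = frozenset("ACGT")

FeatureClass = Literal["CDS", "tRNA", "rRNA", "origin", "noncoding"]
FEATURE_CLASSES = ("CDS", "tRNA", "rRNA", "origin", "noncoding")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV-", "TGCANYRSWMKVHDB-")


class AlignmentShapeError(ValueError):
    """Records of unequal length, or otherwise malformed alignment."""


class InputError(ValueError):
    """Malformed or empty input file / table."""


class RangeError(ValueError):
    """Coordinates outside the alignment."""


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving gaps and IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeAlignment:
    """A multiple alignment of whole mitogenomes (or a partition of one).

    Parameters
    ----------
    sample_ids
        Unique sequence identifiers, in input order.
    sequences
        Upper-case strings over the IUPAC DNA alphabet plus ``-``; all the
        same length.
    column_map
        1-based original coordinate of each column, or None for synthetic /
        coordinate-free alignments.  Length equals the alignment length.
    """

    sample_ids: list[str]
    sequences: list[str]
    column_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise AlignmentShapeError("sample_ids and sequences differ in count")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = {s for s in self.sample_ids if self.sample_ids.count(s) > 1}
            raise AlignmentShapeError(f"duplicate sample ids: {sorted(dupes)}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentShapeError(f"unequal sequence lengths: {sorted(lengths)}")
        if self.column_map is not None:
            self.column_map = np.asarray(self.column_map, dtype=np.int64)
            if self.column_map.shape != (self.length,):
                raise AlignmentShapeError(
                    "column_map length does not match alignment length"
                )

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def matrix(self) -> np.ndarray:
        """(n, L) array of single-character bytes ('S1')."""
        return np.frombuffer(
            "".join(self.sequences).encode(), dtype="S1"
        ).reshape(self.n, self.length)

    def take_columns(self, idx: np.ndarray | Sequence[int]) -> "GenomeAlignment":
        """New alignment keeping columns ``idx`` in the given order."""
        idx = np.asarray(idx, dtype=np.int64)
        mat = self.matrix()[:, idx]
        seqs = [row.tobytes().decode() for row in mat]
        cmap = None if self.column_map is None else self.column_map[idx]
        return GenomeAlignment(list(self.sample_ids), seqs, cmap)

    def subset(self, ids: Iterable[str]) -> "GenomeAlignment":
        """New alignment restricted to the given sample ids (input order kept)."""
        wanted = set(ids)
        missing = wanted - set(self.sample_ids)
        if missing:
            raise InputError(f"sample ids not in alignment: {sorted(missing)}")
        keep = [i for i, s in enumerate(self.sample_ids) if s in wanted]
        cmap = None if self.column_map is None else self.column_map.copy()
        return GenomeAlignment(
            [self.sample_ids[i] for i in keep],
            [self.sequences[i] for i in keep],
            cmap,
        )


@dataclass(frozen=True)
class Feature:
    name: str
    start: int  # 1-based inclusive, original coordinates
    end: int
    strand: str  # '+' or '-'
    klass: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(f"feature {self.name}: start > end")
        if self.strand not in "+-":
            raise InputError(f"feature {self.name}: bad strand {self.strand!r}")
        if self.klass not in FEATURE_CLASSES:
            raise InputError(f"feature {self.name}: unknown class {self.klass!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneAnnotation:
    """Named feature intervals with strand and class; may overlap (ND5/ND6)."""

    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise InputError(f"duplicate feature names: {dupes}")

    def by_class(self, klass: str) -> list[Feature]:
        return [f for f in self.features if f.klass == klass]

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)


@dataclass
class MaskSet:
    """Excluded intervals, 1-based inclusive, on original coordinates."""

    intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        norm: list[tuple[int, int]] = []
        for s, e in sorted(self.intervals):
            if s < 1 or s > e:
                raise InputError(f"bad mask interval ({s}, {e})")
            if norm and s <= norm[-1][1] + 1:
                norm[-1] = (norm[-1][0], max(norm[-1][1], e))
            else:
                norm.append((s, e))
        self.intervals = norm

    def covers(self, positions: np.ndarray) -> np.ndarray:
        """Boolean mask over ``positions`` (1-based original coordinates)."""
        out = np.zeros(len(positions), dtype=bool)
        for s, e in self.intervals:
            out |= (positions >= s) & (positions <= e)
        return out


@dataclass
class LineageTable:
    """sample -> (species, lineage) assignment; lineages nest within species."""

    table: pd.DataFrame  # columns: sample_id, species, lineage

    def __post_init__(self) -> None:
        required = ["sample_id", "species", "lineage"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise InputError(f"lineage table missing columns: {missing}")
        if self.table.empty:
            raise InputError("lineage table is empty")
        if self.table["sample_id"].duplicated().any():
            dupes = self.table.loc[
                self.table["sample_id"].duplicated(), "sample_id"
            ].tolist()
            raise InputError(f"duplicate sample ids in lineage table: {dupes}")
        spp = self.table.groupby("lineage")["species"].nunique()
        bad = spp[spp > 1].index.tolist()
        if bad:
            raise InputError(f"lineages spanning multiple species: {bad}")

    def samples(self, *, species: str | None = None, lineage: str | None = None) -> list[str]:
        df = self.table
        if species is not None:
            df = df[df["species"] == species]
        if lineage is not None:
            df = df[df["lineage"] == lineage]
        return df["sample_id"].tolist()

    def groups(self, level: str = "lineage") -> dict[str, list[str]]:
        """Mapping group label -> sample ids, at 'species' or 'lineage' level."""
        if level not in ("species", "lineage"):
            raise InputError(f"unknown grouping level {level!r}")
        return {
            str(k): g["sample_id"].tolist() for k, g in self.table.groupby(level, sort=False)
        }

    def validate_against(self, aln: GenomeAlignment) -> list[str]:
        """Return sample ids present in the table but absent from the alignment."""
        return sorted(set(self.table["sample_id"]) - set(aln.sample_ids))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path) -> GenomeAlignment:
    """Read an aligned FASTA into a :class:`GenomeAlignment`.

    Bases are upper-cased and U is mapped to T; the column map is the
    identity (columns are original coordinates 1..L).  Raises
    :class:`InputError` on empty files or non-IUPAC characters and
    :class:`AlignmentShapeError` on unequal record lengths.
    """
    path = Path(path)
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - IUPAC_CHARS
        if bad:
            col = min(seq.index(c) for c in bad) + 1
            raise InputError(
                f"record {rec.id!r}: non-IUPAC character {sorted(bad)} "
                f"(first at column {col})"
            )
        ids.append(rec.id)
        seqs.append(seq)
    if not ids:
        raise InputError(f"no FASTA records in {path}")
    aln = GenomeAlignment(ids, seqs)
    aln.column_map = np.arange(1, aln.length + 1, dtype=np.int64)
    return aln


def write_alignment(aln: GenomeAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=sid, description="")
        for sid, s in zip(aln.sample_ids, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Read an annotation from GFF3 (``.gff``/``.gff3``) or 5-column TSV.

    The TSV columns are name, start, end, strand, class with a header row.
    For GFF3, the feature type column supplies the class (``CDS``, ``tRNA``,
    ``rRNA``, ``origin``, ``noncoding``) and the name comes from the
    ``Name=`` or ``ID=`` attribute.
    """
    path = Path(path)
    feats: list[Feature] = []
    if path.suffix.lower() in (".gff", ".gff3"):
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["seqid", "source", "type", "start", "end",
                   "score", "strand", "phase", "attributes"],
        )
        if df.empty:
            raise InputError(f"no features in {path}")
        for _, row in df.iterrows():
            attrs = dict(
                kv.split("=", 1) for kv in str(row["attributes"]).split(";") if "=" in kv
            )
            name = attrs.get("Name", attrs.get("ID"))
            if name is None:
                raise InputError(f"GFF feature without Name/ID at {row['start']}")
            feats.append(Feature(name, int(row["start"]), int(row["end"]),
                                 str(row["strand"]), str(row["type"])))
    else:
        df = pd.read_csv(path, sep="\t")
        required = ["name", "start", "end", "strand", "class"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise InputError(f"annotation TSV missing columns: {missing}")
        for _, row in df.iterrows():
            feats.append(Feature(str(row["name"]), int(row["start"]), int(row["end"]),
                                 str(row["strand"]), str(row["class"])))
    return GeneAnnotation(feats)


def write_annotation(ann: GeneAnnotation, path: str | Path, seqid: str = "mitogenome") -> None:
    """Write GFF3 (by suffix) or the 5-column TSV form."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        lines = ["##gff-version 3"]
        for f in ann:
            lines.append(
                f"{seqid}\tporpopgen\t{f.klass}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t"
                f"ID={f.name};Name={f.name}"
            )
        path.write_text("\n".join(lines) + "\n")
    else:
        df = pd.DataFrame(
            [(f.name, f.start, f.end, f.strand, f.klass) for f in ann],
            columns=["name", "start", "end", "strand", "class"],
        )
        df.to_csv(path, sep="\t", index=False)


def read_mask(path: str | Path, *, coordinates: str = "bed") -> MaskSet:
    """Read mask intervals.

    ``coordinates='bed'`` treats the file as BED (0-based half-open, columns
    chrom/start/end) and converts to internal 1-based inclusive;
    ``coordinates='inclusive'`` reads 2-column 1-based inclusive start/end.
    """
    path = Path(path)
    rows = [
        ln.split("\t") for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith(("#", "track", "browser"))
    ]
    if not rows:
        return MaskSet([])
    intervals = []
    for parts in rows:
        if coordinates == "bed":
            s, e = int(parts[1]), int(parts[2])
            intervals.append((s + 1, e))
        elif coordinates == "inclusive":
            s, e = int(parts[0]), int(parts[1])
            intervals.append((s, e))
        else:
            raise InputError(f"unknown mask coordinate convention {coordinates!r}")
    return MaskSet(intervals)


def write_mask(mask: MaskSet, path: str | Path, seqid: str = "mitogenome") -> None:
    """Write the mask as BED (0-based half-open)."""
    lines = [f"{seqid}\t{s - 1}\t{e}" for s, e in mask.intervals]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_lineage_table(path: str | Path) -> LineageTable:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty lineage table {path}") from exc
    return LineageTable(df)


def write_lineage_table(tab: LineageTable, path: str | Path) -> None:
    tab.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# masking and partition extraction
# ---------------------------------------------------------------------------

def apply_mask(aln: GenomeAlignment, mask: MaskSet) -> GenomeAlignment:
    """Remove masked columns; the column map of survivors is preserved.

    Mask coordinates refer to original coordinates (the alignment's
    ``column_map``), so masking commutes for disjoint masks and is stable
    under repeated application.
    """
    if not mask.intervals:
        return aln.take_columns(np.arange(aln.length))
    if aln.column_map is None:
        raise RangeError("cannot mask an alignment without a column map")
    max_orig = int(aln.column_map.max()) if aln.length else 0
    for s, e in mask.intervals:
        if e > max_orig:
            raise RangeError(f"mask interval ({s}, {e}) outside genome (max {max_orig})")
    keep = ~mask.covers(aln.column_map)
    return aln.take_columns(np.flatnonzero(keep))


def _resolve_feature(aln: GenomeAlignment, feat: Feature) -> np.ndarray:
    """Column indices (genomic order) of a feature through the column map."""
    if aln.column_map is None:
        cmap = np.arange(1, aln.length + 1)
    else:
        cmap = aln.column_map
    if feat.end > (cmap.max() if len(cmap) else 0):
        raise RangeError(f"feature {feat.name} ({feat.start}-{feat.end}) outside alignment")
    return np.flatnonzero((cmap >= feat.start) & (cmap <= feat.end))


def extract_partition(
    aln: GenomeAlignment,
    ann: GeneAnnotation,
    which: Literal["whole", "noncoding", "cds_concat"],
) -> GenomeAlignment:
    """Build an analysis partition of the alignment.

    whole
        The input unchanged.
    noncoding
        Columns covered by no annotated feature (CDS/tRNA/rRNA/origin), in
        genomic order — intergenic spacers plus the control region.
    cds_concat
        Per-gene extraction of every CDS in annotation order: minus-strand
        genes are reverse-complemented, columns shared by overlapping genes
        appear once per gene, and each gene's frame starts at its own first
        codon.  A gene whose extracted length is not a multiple of 3 has its
        incomplete terminal codon dropped with a warning (mitochondrial CDSs
        with incomplete stop codons are common).
    """
    if which == "whole":
        return aln.take_columns(np.arange(aln.length))
    if which == "noncoding":
        covered = np.zeros(aln.length, dtype=bool)
        for feat in ann:
            if feat.klass != "noncoding":  # annotated noncoding stays noncoding
                covered[_resolve_feature(aln, feat)] = True
        return aln.take_columns(np.flatnonzero(~covered))
    if which == "cds_concat":
        ids = list(aln.sample_ids)
        parts: dict[str, list[str]] = {sid: [] for sid in ids}
        cmap_parts: list[np.ndarray] = []
        has_map = aln.column_map is not None
        for feat in ann.by_class("CDS"):
            idx = _resolve_feature(aln, feat)
            block = aln.take_columns(idx)
            seqs = block.sequences
            bmap = block.column_map if has_map else None
            if feat.strand == "-":
                seqs = [reverse_complement(s) for s in seqs]
                bmap = bmap[::-1] if bmap is not None else None
            rem = len(idx) % 3
            if rem:
                warnings.warn(
                    f"CDS {feat.name}: length {len(idx)} not divisible by 3; "
                    f"dropping {rem} terminal base(s)",
                    stacklevel=2,
                )
                seqs = [s[: len(s) - rem] for s in seqs]
                bmap = bmap[: len(bmap) - rem] if bmap is not None else None
            for sid, s in zip(ids, seqs):
                parts[sid].append(s)
            if bmap is not None:
                cmap_parts.append(bmap)
        cmap = np.concatenate(cmap_parts) if (has_map and cmap_parts) else None
        return GenomeAlignment(ids, ["".join(parts[sid]) for sid in ids], cmap)
    raise InputError(f"unknown partition {which!r}")


def gene_blocks(
    aln: GenomeAlignment, ann: GeneAnnotation
) -> dict[str, GenomeAlignment]:
    """Per-CDS alignments, strand-oriented and trimmed to full codons.

    Same extraction rules as ``extract_partition('cds_concat')`` but keeping
    genes separate, for codon-level analyses.
    """
    out: dict[str, GenomeAlignment] = {}
    for feat in ann.by_class("CDS"):
        idx = _resolve_feature(aln, feat)
        block = aln.take_columns(idx)
        seqs = block.sequences
        if feat.strand == "-":
            seqs = [reverse_complement(s) for s in seqs]
        rem = len(idx) % 3
        if rem:
            warnings.warn(
                f"CDS {feat.name}: length {len(idx)} not divisible by 3; "
                f"dropping {rem} terminal base(s)",
                stacklevel=2,
            )
            seqs = [s[: len(s) - rem] for s in seqs]
        out[feat.name] = GenomeAlignment(list(aln.sample_ids), seqs)
    return out
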