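"""Readers and writers for the formats the pipeline touches.

The pipeline consumes per-species proteomes (FASTA), pairwise similarity
hits (BLAST tabular, outfmt-6 column order), gene trees (newick with branch
lengths and support labels), leaf taxonomy maps (TSV) and fractionation
proteomics intensity tables (TSV with ``<fraction>_<replicate>`` columns).
Everything here is deliberately strict: duplicate identifiers, empty
sequences and malformed headers are errors, not warnings, because every
downstream stage keys on unique ids.
"""

from __future__ import annotations

import io as _stdio
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd
import yaml

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

__all__ = [
    "FormatError",
    "SequenceRecord",
    "HitRecord",
    "TaxonMap",
    "RunConfig",
    "IntensityTable",
    "parse_fasta",
    "write_fasta",
    "parse_newick",
    "write_newick",
    "node_support",
    "parse_hits",
    "write_hits",
    "parse_taxon_map",
    "write_taxon_map",
    "parse_intensity_table",
    "write_intensity_table",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with its species of origin.

    ``id`` must be whitespace-free and unique within a proteome; ``seq`` is
    an uppercase amino-acid string (the 20 standard residues plus X).
    """

    id: str
    species: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id or re.search(r"\s", self.id):
            raise FormatError(f"invalid sequence id {self.id!r}")
        if len(self.seq) < 1:
            raise FormatError(f"empty sequence body for id {self.id!r}")
        bad = set(self.seq) - AA_ALPHABET
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains invalid residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class HitRecord:
    """One pairwise similarity hit (BLAST convention, 1-based inclusive)."""

    query_id: str
    subject_id: str
    pident: float
    length: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: start > end"
            )
        if not np.isfinite(self.bitscore) or self.bitscore < 0:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: bad bitscore"
            )
        if self.evalue < 0:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: negative E-value"
            )


class TaxonMap:
    """Leaf id -> (domain, taxon) lookup.

    ``domain`` is ``"eukaryote"`` or ``"prokaryote"``; ``taxon`` is a phylum
    or class token, mandatory for prokaryotes and optional for eukaryotes.
    """

    DOMAINS = ("eukaryote", "prokaryote")

    def __init__(self, entries: Mapping[str, tuple[str, str]]):
        self._entries: dict[str, tuple[str, str]] = {}
        for leaf_id, (domain, taxon) in entries.items():
            if domain not in self.DOMAINS:
                raise FormatError(f"unknown domain {domain!r} for {leaf_id!r}")
            if domain == "prokaryote" and not taxon:
                raise FormatError(f"prokaryote {leaf_id!r} lacks a taxon")
            self._entries[leaf_id] = (domain, taxon)

    def __contains__(self, leaf_id: str) -> bool:
        return leaf_id in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)

    def domain(self, leaf_id: str) -> str:
        return self._entries[leaf_id][0]

    def taxon(self, leaf_id: str) -> str:
        return self._entries[leaf_id][1]

    def is_eukaryote(self, leaf_id: str) -> bool:
        return self.domain(leaf_id) == "eukaryote"

    def items(self):
        return self._entries.items()


@dataclass
class RunConfig:
    """Resolved run configuration; the seed is echoed into every output."""

    positive: list[str] = field(default_factory=list)
    negative: list[str] = field(default_factory=list)
    exempt: list[str] = field(default_factory=list)
    required_all: list[str] = field(default_factory=list)
    min_edge_support: int = 1
    evalue_cutoff: float = 1e-5
    c_hi: float = 0.99
    c_lo: float = 0.70
    c_step: float = 0.01
    cluster_quantile: float = 0.99
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        panels = [set(self.positive), set(self.negative), set(self.exempt)]
        for i in range(3):
            for j in range(i + 1, 3):
                if panels[i] & panels[j]:
                    raise ValueError(
                        "species panel lists must be pairwise disjoint; "
                        f"shared: {sorted(panels[i] & panels[j])}"
                    )
        if not set(self.required_all) <= set(self.positive):
            raise ValueError("required_all must be a subset of positive")
        if not (0 < self.c_step <= self.c_hi - self.c_lo):
            raise ValueError("need 0 < c_step <= c_hi - c_lo")

    @classmethod
    def from_yaml(cls, stream: IO[str] | str) -> "RunConfig":
        data = yaml.safe_load(stream) or {}
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.__dict__, sort_keys=True)

    def header_lines(self) -> list[str]:
        """Comment lines recording the resolved config, seed included."""
        return [
            f"# copresence seed={self.seed}",
            "# config: " + yaml.safe_dump(self.__dict__, default_flow_style=True).strip(),
        ]


# ---------------------------------------------------------------------------
# FASTA


def _as_text_stream(stream: IO[str] | str) -> IO[str]:
    if isinstance(stream, str):
        return _stdio.StringIO(stream)
    return stream


def parse_fasta(
    stream: IO[str] | str,
    species_map: Mapping[str, str] | None = None,
    species_regex: str = r"sp=(\S+)",
) -> list[SequenceRecord]:
    """Parse a FASTA stream into :class:`SequenceRecord` objects.

    The species of each record is taken from ``species_map`` (id -> species)
    when given, otherwise extracted from the header description with
    ``species_regex`` (default matches the ``sp=TOKEN`` dialect). Records
    with no resolvable species get species ``""``.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    handle = _as_text_stream(stream)
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        fields = header.split(None, 1)
        seq_id = fields[0]
        if seq_id in seen:
            raise FormatError(f"duplicate sequence id {seq_id!r}")
        seen.add(seq_id)
        seq = "".join(chunks).upper()
        if not seq:
            raise FormatError(f"empty sequence body for id {seq_id!r}")
        if species_map is not None:
            species = species_map.get(seq_id, "")
        else:
            m = re.search(species_regex, header)
            species = m.group(1) if m else ""
        records.append(SequenceRecord(id=seq_id, species=species, seq=seq))

    for line in handle:
        line = line.rstrip("\n")
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            if not header:
                raise FormatError("FASTA header with empty id")
            chunks = []
        elif line.strip():
            if header is None:
                raise FormatError("sequence data before first FASTA header")
            chunks.append(line.strip())
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], stream: IO[str], width: int = 60) -> None:
    for rec in records:
        stream.write(f">{rec.id} sp={rec.species}\n")
        for i in range(0, len(rec.seq), width):
            stream.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Newick


def parse_newick(stream: IO[str] | str, rooted: bool | None = None) -> dendropy.Tree:
    """Parse one newick statement into a dendropy tree.

    Leaf names are preserved exactly (underscores are not turned into
    spaces); internal-node labels carry support values as plain strings;
    missing branch lengths stay ``None``. Structural errors (unbalanced
    parentheses, missing terminator) raise :class:`FormatError` with the
    approximate character offset.
    """
    text = stream if isinstance(stream, str) else stream.read()
    stripped = text.strip()
    if not stripped:
        raise FormatError("empty newick input at offset 0")
    if not stripped.endswith(";"):
        raise FormatError(
            f"newick statement not terminated by ';' at offset {len(text)}"
        )
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(f"unbalanced ')' at offset {offset}")
    if depth != 0:
        raise FormatError(f"unbalanced '(' ({depth} unclosed) at offset {len(text)}")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise FormatError(f"newick parse error: {exc}") from exc
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise FormatError("empty leaf name in newick input")
    if rooted is not None:
        tree.is_rooted = rooted
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialise with plain internal labels; inverse of :func:`parse_newick`."""
    return (
        tree.as_string(
            schema="newick",
            unquoted_underscores=True,
            suppress_rooting=True,
        ).strip()
        + "\n"
    )


def node_support(node: dendropy.Node) -> float | None:
    """Support label of an internal node as a float, or None if absent."""
    if node.label is None or node.label == "":
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# Hits (outfmt-6)

OUTFMT6_COLUMNS = [
    "query_id",
    "subject_id",
    "pident",
    "length",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bitscore",
]


def parse_hits(stream: IO[str] | str) -> list[HitRecord]:
    """Read a BLAST outfmt-6-like TSV (qseqid sseqid pident length qstart
    qend sstart send evalue bitscore) into :class:`HitRecord` objects."""
    df = pd.read_csv(
        _as_text_stream(stream),
        sep="\t",
        names=OUTFMT6_COLUMNS,
        header=None,
        comment="#",
    )
    return [
        HitRecord(
            query_id=str(r.query_id),
            subject_id=str(r.subject_id),
            pident=float(r.pident),
            length=int(r.length),
            q_start=int(r.q_start),
            q_end=int(r.q_end),
            s_start=int(r.s_start),
            s_end=int(r.s_end),
            evalue=float(r.evalue),
            bitscore=float(r.bitscore),
        )
        for r in df.itertuples(index=False)
    ]


def write_hits(hits: Iterable[HitRecord], stream: IO[str]) -> None:
    for h in hits:
        stream.write(
            "\t".join(
                str(v)
                for v in (
                    h.query_id,
                    h.subject_id,
                    f"{h.pident:.2f}",
                    h.length,
                    h.q_start,
                    h.q_end,
                    h.s_start,
                    h.s_end,
                    f"{h.evalue:.3g}",
                    f"{h.bitscore:.1f}",
                )
            )
            + "\n"
        )


# ---------------------------------------------------------------------------
# Taxon map


def parse_taxon_map(stream: IO[str] | str) -> TaxonMap:
    """TSV with columns ``id``, ``domain``, ``taxon`` (header optional)."""
    entries: dict[str, tuple[str, str]] = {}
    for lineno, line in enumerate(_as_text_stream(stream), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if lineno == 1 and parts[0].lower() in ("id", "leaf_id"):
            continue
        if len(parts) < 2:
            raise FormatError(f"taxon map line {lineno}: expected >=2 columns")
        leaf_id, domain = parts[0], parts[1]
        taxon = parts[2] if len(parts) > 2 else ""
        if leaf_id in entries:
            raise FormatError(f"duplicate id {leaf_id!r} in taxon map")
        entries[leaf_id] = (domain, taxon)
    return TaxonMap(entries)


def write_taxon_map(tmap: TaxonMap, stream: IO[str]) -> None:
    stream.write("id\tdomain\ttaxon\n")
    for leaf_id, (domain, taxon) in tmap.items():
        stream.write(f"{leaf_id}\t{domain}\t{taxon}\n")


# ---------------------------------------------------------------------------
# Intensity table


class IntensityTable:
    """Protein x (fraction, replicate) intensity matrix with a missing mask.

    ``data`` is a float DataFrame indexed by protein id with a two-level
    column MultiIndex ``(fraction, replicate)``; missing measurements are
    NaN. Observed intensities must be non-negative on the raw scale; after
    a log2 transform (:meth:`log2`) negative values are expected and the
    non-negativity invariant is waived.
    """

    def __init__(self, data: pd.DataFrame, *, is_log2: bool = False):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate protein ids: {dups}")
        if data.columns.nlevels != 2:
            raise ValueError("columns must be a (fraction, replicate) MultiIndex")
        values = data.to_numpy(dtype=float)
        if not is_log2 and np.nanmin(values, initial=0.0) < 0:
            raise FormatError("negative intensity on the raw scale")
        self.data = data.astype(float)
        self.is_log2 = is_log2

    @property
    def proteins(self) -> pd.Index:
        return self.data.index

    @property
    def fractions(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(0)))

    @property
    def replicates(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(1)))

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def log2(self) -> "IntensityTable":
        """Log2-transform; zeros become missing (log of zero is undefined)."""
        if self.is_log2:
            return self
        with np.errstate(divide="ignore"):
            out = np.log2(self.data.where(self.data > 0))
        return IntensityTable(out, is_log2=True)

    def copy(self) -> "IntensityTable":
        return IntensityTable(self.data.copy(), is_log2=self.is_log2)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntensityTable):
            return NotImplemented
        return self.is_log2 == other.is_log2 and self.data.equals(other.data)


_COLUMN_RE = re.compile(r"^(?P<fraction>.+)_(?P<replicate>[^_]+)$")


def parse_intensity_table(
    stream: IO[str] | str, *, zero_is_missing: bool = False
) -> IntensityTable:
    """Parse a TSV intensity table into an :class:`IntensityTable`.

    First column: protein id. Remaining columns: ``<fraction>_<replicate>``.
    Empty cells and the literal strings ``NaN``/``NA`` are missing; a
    literal 0 is a valid measurement unless ``zero_is_missing`` is set.
    """
    df = pd.read_csv(
        _as_text_stream(stream),
        sep="\t",
        index_col=0,
        na_values=["NaN", "NA", ""],
        keep_default_na=False,
        comment="#",
    )
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate protein ids: {dups}")
    tuples = []
    for col in df.columns:
        m = _COLUMN_RE.match(str(col))
        if not m:
            raise FormatError(
                f"column {col!r} does not match <fraction>_<replicate>"
            )
        tuples.append((m.group("fraction"), m.group("replicate")))
    df.columns = pd.MultiIndex.from_tuples(tuples, names=["fraction", "replicate"])
    df = df.astype(float)
    if zero_is_missing:
        df = df.where(df != 0)
    return IntensityTable(df)


def write_intensity_table(table: IntensityTable, stream: IO[str]) -> None:
    flat = table.data.copy()
    flat.columns = [f"{f}_{r}" for f, r in table.data.columns]
    flat.index.name = "protein"
    flat.to_csv(stream, sep="\t", na_rep="NaN")
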