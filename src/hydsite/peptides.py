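"""Protein records, peptide windows, and benchmark dataset construction.

A candidate hydroxylation site is a Pro (P) or Lys (K) residue.  Around each
occurrence of the target residue a (2*xi + 1)-mer peptide window is cut out,
with positions beyond the protein termini filled by the dummy residue ``X``.
Windows whose center is an experimentally verified site form the positive
subset, the rest the negative subset; the two subsets are then screened for
within-subset duplicates and for "self-conflict" windows that occur in both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

#: The 20 standard amino-acid one-letter codes, in the conventional order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Dummy residue filling window slots that fall outside the protein termini.
DUMMY = "X"

#: Working alphabet: 20 standard residues plus the dummy X (21 symbols).
ALPHABET = AMINO_ACIDS + DUMMY

_STANDARD = frozenset(AMINO_ACIDS)


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class ParseError(ValueError):
    """Raised when an on-disk file does not match its documented dialect."""


def normalize_sequence(raw: str) -> str:
    """Uppercase a sequence and map every non-standard letter to ``X``.

    Non-standard codes (B, J, O, U, Z, ``*``, gaps, ...) are mapped to the
    dummy residue rather than rejected, so real-world FASTA files survive.
    Whitespace is removed.
    """
    seq = "".join(raw.split()).upper()
    return "".join(c if c in _STANDARD else DUMMY for c in seq)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an accession-like identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"protein {self.id!r} has an empty sequence")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValidationError(
                f"protein {self.id!r} contains unnormalized symbols {sorted(bad)}; "
                "run normalize_sequence first"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotatedProtein:
    """A protein plus the 1-based positions of verified hydroxylation sites."""

    protein: ProteinRecord
    sites: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", frozenset(self.sites))
        for pos in self.sites:
            if not 1 <= pos <= len(self.protein):
                raise ValidationError(
                    f"site position {pos} out of range for protein "
                    f"{self.protein.id!r} of length {len(self.protein)}"
                )


@dataclass(frozen=True)
class PeptideSample:
    """A (2*xi+1)-mer window centered on a candidate site.

    ``center_position`` is 1-based on the source protein; window indexing is
    0-based, the center sitting at index ``xi``.
    """

    window: str
    center: str
    label: str  # "positive" | "negative"
    source_id: str
    center_position: int

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative"):
            raise ValidationError(f"bad label {self.label!r}")
        if len(self.window) % 2 == 0:
            raise ValidationError("window length must be odd (2*xi + 1)")
        if self.window[len(self.window) // 2] != self.center:
            raise ValidationError(
                f"window {self.window!r} is not centered on {self.center!r}"
            )

    @property
    def xi(self) -> int:
        return len(self.window) // 2

    @property
    def is_positive(self) -> bool:
        return self.label == "positive"


@dataclass(frozen=True)
class BenchmarkDataset:
    """Screened positive/negative peptide subsets for one target residue."""

    target: str
    xi: int
    positives: tuple[PeptideSample, ...]
    negatives: tuple[PeptideSample, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "positives", tuple(self.positives))
        object.__setattr__(self, "negatives", tuple(self.negatives))
        width = 2 * self.xi + 1
        for s in self.positives + self.negatives:
            if len(s.window) != width:
                raise ValidationError(
                    f"window {s.window!r} has length {len(s.window)}, "
                    f"expected {width} for xi={self.xi}"
                )
            if s.center != self.target:
                raise ValidationError(
                    f"sample centered on {s.center!r} in a {self.target!r} dataset"
                )
        pos_w = [s.window for s in self.positives]
        neg_w = [s.window for s in self.negatives]
        if len(set(pos_w)) != len(pos_w) or len(set(neg_w)) != len(neg_w):
            raise ValidationError("duplicate windows within a subset")
        if set(pos_w) & set(neg_w):
            raise ValidationError("self-conflict windows present in both subsets")

    def __len__(self) -> int:
        return len(self.positives) + len(self.negatives)


def _check_target(target: str) -> str:
    target = target.upper()
    if len(target) != 1 or target not in _STANDARD:
        raise ValidationError(f"target residue must be a standard amino acid, got {target!r}")
    return target


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into normalized :class:`ProteinRecord` objects.

    Sequences are uppercased and non-standard letters mapped to ``X``; the
    file order is preserved.  An empty file or an entry with an empty
    sequence raises :class:`ValidationError`.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(rec.seq))
        if not seq:
            raise ValidationError(f"FASTA record {rec.id!r} in {path} has an empty sequence")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValidationError(f"no FASTA records found in {path}")
    return records


def read_sites(path: str | Path) -> dict[str, frozenset[int]]:
    """Read a site-annotation TSV (columns ``protein_id``, ``position``).

    A header line is required; positions are 1-based.  Returns a mapping
    protein id -> set of positions.
    """
    path = Path(path)
    sites: dict[str, set[int]] = {}
    with open(path) as fh:
        header = fh.readline()
        cols = header.rstrip("\n").split("\t")
        if cols[:2] != ["protein_id", "position"]:
            raise ParseError(
                f"{path}:1: expected header 'protein_id\\tposition', got {header.strip()!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
            try:
                pos = int(parts[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: position {parts[1]!r} is not an integer")
            sites.setdefault(parts[0], set()).add(pos)
    return {k: frozenset(v) for k, v in sites.items()}


def annotate(proteins: Sequence[ProteinRecord],
             sites: dict[str, frozenset[int]]) -> list[AnnotatedProtein]:
    """Pair proteins with their annotated site positions (missing -> empty)."""
    return [AnnotatedProtein(p, sites.get(p.id, frozenset())) for p in proteins]


def extract_samples(protein: AnnotatedProtein, target: str, xi: int) -> list[PeptideSample]:
    """Slide a (2*xi+1)-mer window over every occurrence of ``target``.

    Out-of-range window slots are filled with ``X``.  A sample is labeled
    positive iff its center position is annotated as a site.  Samples are
    returned in order of center position.
    """
    target = _check_target(target)
    if xi < 1:
        raise ValidationError(f"xi must be >= 1, got {xi}")
    seq = protein.protein.sequence
    for pos in protein.sites:
        if seq[pos - 1] != target:
            raise ValidationError(
                f"annotated site {pos} in protein {protein.protein.id!r} is "
                f"{seq[pos - 1]!r}, not the target residue {target!r}"
            )
    padded = DUMMY * xi + seq + DUMMY * xi
    samples = []
    for i, residue in enumerate(seq):
        if residue != target:
            continue
        center_position = i + 1
        window = padded[i : i + 2 * xi + 1]
        label = "positive" if center_position in protein.sites else "negative"
        samples.append(
            PeptideSample(
                window=window,
                center=target,
                label=label,
                source_id=protein.protein.id,
                center_position=center_position,
            )
        )
    return samples


@dataclass(frozen=True)
class ScreeningLog:
    """Bookkeeping for the benchmark screening step."""

    total_windows: int
    duplicate_positives: int
    duplicate_negatives: int
    conflict_positives: int
    conflict_negatives: int


def build_benchmark(proteins: Iterable[AnnotatedProtein], target: str, xi: int,
                    return_log: bool = False):
    """Assemble a screened :class:`BenchmarkDataset` from annotated proteins.

    Screening: within each subset, duplicate window strings are removed
    keeping the first occurrence in input order; any window string occurring
    in both subsets (a self-conflict) is then removed from both.
    """
    target = _check_target(target)
    pos_raw: list[PeptideSample] = []
    neg_raw: list[PeptideSample] = []
    for ap in proteins:
        for s in extract_samples(ap, target, xi):
            (pos_raw if s.is_positive else neg_raw).append(s)

    def dedupe(samples: list[PeptideSample]) -> tuple[list[PeptideSample], int]:
        seen: set[str] = set()
        kept = []
        for s in samples:
            if s.window not in seen:
                seen.add(s.window)
                kept.append(s)
        return kept, len(samples) - len(kept)

    pos, dup_pos = dedupe(pos_raw)
    neg, dup_neg = dedupe(neg_raw)
    conflicts = {s.window for s in pos} & {s.window for s in neg}
    pos_kept = [s for s in pos if s.window not in conflicts]
    neg_kept = [s for s in neg if s.window not in conflicts]
    if not pos_kept or not neg_kept:
        raise ValidationError(
            "screened benchmark has an empty subset "
            f"({len(pos_kept)} positives, {len(neg_kept)} negatives); "
            "it cannot support model fitting"
        )
    dataset = BenchmarkDataset(target=target, xi=xi,
                               positives=tuple(pos_kept), negatives=tuple(neg_kept))
    if return_log:
        log = ScreeningLog(
            total_windows=len(pos_raw) + len(neg_raw),
            duplicate_positives=dup_pos,
            duplicate_negatives=dup_neg,
            conflict_positives=len(pos) - len(pos_kept),
            conflict_negatives=len(neg) - len(neg_kept),
        )
        return dataset, log
    return dataset


# ---------------------------------------------------------------------------
# Benchmark file I/O.  Primary dialect: FASTA with headers
#   >sourceID|centerPosition|pos   (or |neg)
# Secondary dialect: TSV with a header line
#   window  label  source_id  center_position
# Auto-detected on read by the first non-blank character ('>' -> FASTA).
# ---------------------------------------------------------------------------

_LABELS = {"pos": "positive", "neg": "negative"}
_TAGS = {"positive": "pos", "negative": "neg"}


def write_benchmark(dataset: BenchmarkDataset, path: str | Path) -> None:
    """Write a benchmark dataset in the FASTA dialect (round-trip exact)."""
    path = Path(path)
    with open(path, "w") as fh:
        for s in dataset.positives + dataset.negatives:
            fh.write(f">{s.source_id}|{s.center_position}|{_TAGS[s.label]}\n{s.window}\n")


def _samples_to_dataset(samples: list[PeptideSample], target: str, xi: int,
                        path: Path) -> BenchmarkDataset:
    width = 2 * xi + 1
    for s in samples:
        if len(s.window) != width:
            raise ValidationError(
                f"{path}: window {s.window!r} has length {len(s.window)}, "
                f"inconsistent with xi={xi} (expected {width})"
            )
        if s.center != target:
            raise ValidationError(
                f"{path}: window {s.window!r} centered on {s.center!r}, "
                f"expected target {target!r}"
            )
    return BenchmarkDataset(
        target=target, xi=xi,
        positives=tuple(s for s in samples if s.is_positive),
        negatives=tuple(s for s in samples if not s.is_positive),
    )


def read_benchmark(path: str | Path, target: str, xi: int) -> BenchmarkDataset:
    """Read a benchmark peptide file (FASTA or TSV dialect, auto-detected)."""
    target = _check_target(target)
    path = Path(path)
    text = path.read_text()
    first = text.lstrip()[:1]
    if not first:
        raise ParseError(f"{path}: empty benchmark file")
    samples: list[PeptideSample] = []
    if first == ">":
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.id.rsplit("|", 2)
            if len(parts) != 3 or parts[2] not in _LABELS:
                raise ParseError(
                    f"{path}: header {rec.id!r} does not match 'sourceID|position|pos/neg'"
                )
            try:
                center_position = int(parts[1])
            except ValueError:
                raise ParseError(f"{path}: non-integer position in header {rec.id!r}")
            window = normalize_sequence(str(rec.seq))
            samples.append(
                PeptideSample(window=window, center=window[len(window) // 2],
                              label=_LABELS[parts[2]], source_id=parts[0],
                              center_position=center_position)
            )
    else:
        lines = text.splitlines()
        cols = lines[0].split("\t")
        if cols[:4] != ["window", "label", "source_id", "center_position"]:
            raise ParseError(
                f"{path}:1: expected header 'window\\tlabel\\tsource_id\\tcenter_position'"
            )
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 tab-separated columns")
            window, label, source_id, center_position = parts[:4]
            if label not in _LABELS:
                raise ParseError(f"{path}:{lineno}: label must be 'pos' or 'neg', got {label!r}")
            try:
                pos_i = int(center_position)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer center_position {center_position!r}")
            window = normalize_sequence(window)
            samples.append(
                PeptideSample(window=window, center=window[len(window) // 2],
                              label=_LABELS[label], source_id=source_id,
                              center_position=pos_i)
            )
    if not samples:
        raise ParseError(f"{path}: no peptide samples found")
    return _samples_to_dataset(samples, target, xi, path)
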