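"""Labeled FASTA I/O, sequence sanitization, length normalization and
synthetic dataset generation.

Sequences are amino-acid strings over the 20 standard one-letter codes.
Binary toxicity labels (toxic = 1, nontoxic = 0) ride in the FASTA header
after a ``|`` separator by default, or in a sidecar two-column TSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"  # alphabetical one-letter codes
AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}

#: substitutions for the "map" nonstandard-residue policy
_AMBIGUOUS_MAP = {"B": "D", "Z": "E", "U": "C", "J": "L", "O": "K"}

DEFAULT_MAX_LEN = 1002


class SequenceError(ValueError):
    """Raised for unusable sequence data (empty after cleaning, bad residue)."""


@dataclass
class SequenceRecord:
    """One amino-acid sequence with an identifier and optional binary label."""

    id: str
    residues: str
    label: int | None = None

    def __post_init__(self):
        if self.label is not None:
            self.label = int(self.label)
            if self.label not in (0, 1):
                raise ValueError(f"label must be 0 or 1, got {self.label}")

    def __len__(self) -> int:
        return len(self.residues)


def sanitize_sequence(raw: str, policy: str = "drop") -> str:
    """Uppercase and resolve nonstandard residues.

    policy "drop": remove every character outside the 20-letter alphabet
    (gaps, X, ambiguity codes).  policy "map": substitute ambiguity codes
    by their closest standard residue (B->D, Z->E, U->C, J->L, O->K) and
    drop anything else.
    """
    if policy not in ("drop", "map"):
        raise ValueError(f"unknown sanitization policy {policy!r}")
    cleaned = []
    for ch in raw.upper():
        if ch in AA_INDEX:
            cleaned.append(ch)
        elif policy == "map" and ch in _AMBIGUOUS_MAP:
            cleaned.append(_AMBIGUOUS_MAP[ch])
    result = "".join(cleaned)
    if not result:
        raise SequenceError(f"sequence empty after sanitization: {raw!r}")
    return result


def _parse_label_token(token: str) -> int:
    token = token.strip().lower()
    if token in ("1", "toxic", "pos", "positive", "true"):
        return 1
    if token in ("0", "nontoxic", "neg", "negative", "false"):
        return 0
    raise ValueError(f"cannot parse label token {token!r}")


def read_fasta(
    path: str | Path,
    label_scheme: str = "pipe",
    sidecar: str | Path | None = None,
    sanitize_policy: str = "drop",
) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, in file order.

    label_scheme "pipe": the header is ``id|label``; "none": no labels.
    A sidecar TSV (``id<TAB>label``) overrides header labels when given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar_labels: dict[str, int] = {}
    if sidecar is not None:
        for line in Path(sidecar).read_text().splitlines():
            if not line.strip():
                continue
            rid, _, tok = line.partition("\t")
            sidecar_labels[rid.strip()] = _parse_label_token(tok)

    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        header = entry.description or entry.id
        label: int | None = None
        rid = header
        if label_scheme == "pipe" and "|" in header:
            rid, _, tok = header.rpartition("|")
            try:
                label = _parse_label_token(tok)
            except ValueError:
                rid, label = header, None
        elif label_scheme not in ("pipe", "none"):
            raise ValueError(f"unknown label_scheme {label_scheme!r}")
        if rid in sidecar_labels:
            label = sidecar_labels[rid]
        residues = sanitize_sequence(str(entry.seq), policy=sanitize_policy)
        records.append(SequenceRecord(id=rid, residues=residues, label=label))
    if not records:
        warnings.warn(f"no FASTA entries found in {path}", stacklevel=2)
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA; labels are appended to headers as ``id|label``."""
    bio_records = []
    for rec in records:
        header = rec.id if rec.label is None else f"{rec.id}|{rec.label}"
        bio_records.append(SeqRecord(Seq(rec.residues), id=header, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(bio_records)


def write_label_table(records: list[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.label is not None:
                fh.write(f"{rec.id}\t{rec.label}\n")


def truncate_or_pad(
    record: SequenceRecord, max_len: int = DEFAULT_MAX_LEN, pad_char: str = "-"
) -> tuple[SequenceRecord, np.ndarray]:
    """Normalize a record to exactly ``max_len`` positions.

    Truncation keeps the N-terminal prefix; padding is appended at the
    C-terminal end.  Returns the normalized record and a 0/1 mask marking
    real positions.
    """
    if max_len < 1:
        raise ValueError(f"max_len must be >= 1, got {max_len}")
    n_real = min(len(record.residues), max_len)
    residues = record.residues[:n_real] + pad_char * (max_len - n_real)
    mask = np.zeros(max_len, dtype=np.float64)
    mask[:n_real] = 1.0
    return SequenceRecord(id=record.id, residues=residues, label=record.label), mask


@dataclass
class SyntheticDatasetSpec:
    """Parameters of the synthetic labeled dataset generator.

    Positives carry a short planted motif at a random position with
    probability ``motif_rate``; negatives are uniform random sequences and
    may contain the motif only by chance — so the motif is a known,
    tunable toxicity signal.
    """

    n_positive: int = 200
    n_negative: int = 200
    length_range: tuple[int, int] = (20, 50)
    motif: str = "KWKWK"
    motif_rate: float = 1.0
    seed: int = 0
    aa_weights: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        lo, hi = self.length_range
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("class counts must be non-negative")
        if lo > hi or lo < 1:
            raise ValueError(f"invalid length_range {self.length_range}")
        if not 0.0 <= self.motif_rate <= 1.0:
            raise ValueError(f"motif_rate must be in [0, 1], got {self.motif_rate}")
        if self.motif and any(ch not in AA_INDEX for ch in self.motif):
            raise ValueError(f"motif {self.motif!r} contains nonstandard residues")
        if len(self.motif) > lo:
            raise ValueError(f"motif longer than minimum sequence length {lo}")


def generate_synthetic_dataset(spec: SyntheticDatasetSpec) -> list[SequenceRecord]:
    """Generate a labeled synthetic dataset; deterministic given spec.seed."""
    rng = np.random.default_rng(spec.seed)
    alphabet = np.array(list(STANDARD_AA))
    weights = spec.aa_weights
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()

    def random_seq(length: int) -> str:
        return "".join(rng.choice(alphabet, size=length, p=weights))

    lo, hi = spec.length_range
    records: list[SequenceRecord] = []
    for i in range(spec.n_positive):
        length = int(rng.integers(lo, hi + 1))
        seq = random_seq(length)
        if spec.motif and rng.random() < spec.motif_rate:
            pos = int(rng.integers(0, length - len(spec.motif) + 1))
            seq = seq[:pos] + spec.motif + seq[pos + len(spec.motif) :]
        records.append(SequenceRecord(id=f"pos_{i}", residues=seq, label=1))
    for i in range(spec.n_negative):
        length = int(rng.integers(lo, hi + 1))
        records.append(SequenceRecord(id=f"neg_{i}", residues=random_seq(length), label=0))
    return records
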