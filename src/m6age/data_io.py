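"""Reading, validation and splitting of labeled RNA segment datasets.

Samples are fixed-length RNA segments with the candidate adenosine at the
center position; positives carry experimentally annotated m6A sites. The
primary on-disk interface is a pair of FASTA files (positive / negative);
a single FASTA with ``|label=0/1`` header suffixes is also accepted.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

VALID_ALPHABET = frozenset("ACGU")


@dataclass(frozen=True)
class RnaSample:
    """One RNA segment with a binary m6A label.

    The sequence is stored normalized: upper case, T replaced by U.
    """

    id: str
    sequence: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal characters {sorted(bad)} "
                "(allowed: A, C, G, U; T is converted on read)"
            )

    @property
    def center(self) -> str:
        return self.sequence[len(self.sequence) // 2]


@dataclass
class SampleSet:
    """An ordered collection of equal-length RNA samples with unique ids.

    ``relaxed=True`` keeps only the equal-length and unique-id checks —
    useful for encoding arbitrary short sequences outside the m6A segment
    conventions (odd length, centered A).
    """

    samples: list[RnaSample]
    strict_center: bool = False
    relaxed: bool = False

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("SampleSet must contain at least one sample")
        L = len(self.samples[0].sequence)
        if not self.relaxed and (L < 5 or L % 2 == 0):
            raise ValueError(f"segment length must be odd and >= 5, got {L}")
        seen: set[str] = set()
        for s in self.samples:
            if len(s.sequence) != L:
                raise ValueError(
                    f"record {s.id!r} has length {len(s.sequence)}, expected {L}"
                )
            if s.id in seen:
                raise ValueError(f"duplicate sample id {s.id!r}")
            seen.add(s.id)
        if self.relaxed:
            return
        off_center = [s.id for s in self.samples if s.center != "A"]
        if off_center:
            msg = (
                f"{len(off_center)} sample(s) lack an A at the center position "
                f"(first: {off_center[0]!r})"
            )
            if self.strict_center:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)

    @property
    def seq_length(self) -> int:
        return len(self.samples[0].sequence)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.samples]

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)

    @property
    def sequences(self) -> list[str]:
        return [s.sequence for s in self.samples]

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[RnaSample]:
        return iter(self.samples)

    def subset(self, indices: Iterable[int]) -> "SampleSet":
        return SampleSet([self.samples[i] for i in indices],
                         strict_center=self.strict_center,
                         relaxed=self.relaxed)


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition parameters (default 4:1, stratified, seeded)."""

    train_fraction: float = 0.8
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(
                f"train_fraction must lie in (0, 1), got {self.train_fraction}"
            )


def normalize_sequence(raw: str, record_id: str = "?") -> str:
    """Upper-case and convert T to U; reject anything outside ACGTU."""
    seq = raw.upper().replace("T", "U")
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise ValueError(
            f"record {record_id!r}: illegal characters {sorted(bad)}"
        )
    return seq


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _read_fasta(path: str | Path, label: int | None) -> list[RnaSample]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    samples: list[RnaSample] = []
    with _open_maybe_gzip(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            rec_label = label
            rec_id = rec.id
            if label is None:
                # single-file mode: label encoded as "|label=0/1" in header
                desc = rec.description
                if "|label=" not in desc:
                    raise ValueError(
                        f"record {rec.id!r}: no '|label=' tag in header and "
                        "no per-file label given"
                    )
                tag = desc.rsplit("|label=", 1)[1].strip()
                rec_label = int(tag[0])
                rec_id = rec.id.rsplit("|label=", 1)[0]
            seq = normalize_sequence(str(rec.seq), rec.id)
            samples.append(RnaSample(rec_id, seq, rec_label))
    if not samples:
        raise ValueError(f"FASTA file {path} contains no records")
    return samples


def read_fasta_samples(path_pos: str | Path, path_neg: str | Path,
                       strict_center: bool = False) -> SampleSet:
    """Read a positive and a negative FASTA file into one SampleSet.

    Sequences are normalized (upper case, T->U); labels are 1 for records
    from ``path_pos`` and 0 for records from ``path_neg``. All records must
    share one odd length; a mixed length raises with the offending id.
    """
    pos = _read_fasta(path_pos, 1)
    neg = _read_fasta(path_neg, 0)
    return SampleSet(pos + neg, strict_center=strict_center)


def read_labeled_fasta(path: str | Path, strict_center: bool = False) -> SampleSet:
    """Read a single FASTA whose headers carry ``|label=0/1`` suffixes."""
    return SampleSet(_read_fasta(path, None), strict_center=strict_center)


def write_fasta(data: SampleSet, path_pos: str | Path, path_neg: str | Path) -> None:
    """Write a SampleSet back to a positive / negative FASTA pair."""
    with open(path_pos, "w") as fp, open(path_neg, "w") as fn:
        for s in data:
            handle = fp if s.label == 1 else fn
            handle.write(f">{s.id}\n{s.sequence}\n")


def write_tsv(data: SampleSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\tsequence\n")
        for s in data:
            fh.write(f"{s.id}\t{s.label}\t{s.sequence}\n")


def split_dataset(data: SampleSet, spec: SplitSpec) -> tuple[SampleSet, SampleSet]:
    """Partition a SampleSet into disjoint train/test subsets.

    Stratified by default so the class ratio of the input is preserved in
    both parts (the imbalanced-data protocol depends on this); deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    labels = data.labels
    if spec.stratified:
        for cls in (0, 1):
            if int((labels == cls).sum()) < 5:
                raise ValueError(
                    "stratified split needs >= 5 samples per class; "
                    f"class {cls} has {(labels == cls).sum()}"
                )
        train_idx: list[int] = []
        test_idx: list[int] = []
        for cls in (0, 1):
            cls_idx = np.flatnonzero(labels == cls)
            perm = rng.permutation(cls_idx)
            n_train = round(len(perm) * spec.train_fraction)
            train_idx.extend(perm[:n_train].tolist())
            test_idx.extend(perm[n_train:].tolist())
        train_idx.sort()
        test_idx.sort()
    else:
        perm = rng.permutation(len(data))
        n_train = round(len(data) * spec.train_fraction)
        train_idx = sorted(perm[:n_train].tolist())
        test_idx = sorted(perm[n_train:].tolist())
    return data.subset(train_idx), data.subset(test_idx)
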