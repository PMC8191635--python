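"""Sequence-derived feature encoders for fixed-length RNA segments.

Seven encoders are provided, each returning a named :class:`FeatureBlock`:

========  ====================================================  ==========
tag       what it measures                                      width
========  ====================================================  ==========
CTD       composition / transition / distribution descriptors   30
PseKNC    k-mer frequencies + lambda sequence-order tiers       4^k+lambda
NPS       k-spaced ordered nucleotide-pair frequencies          16*d_max
NPPS      position-specific pair-vs-single conditional          L-k-1
          probability contrast (positives minus negatives)      (per k)
NCP_ND    nucleotide chemical-property bits + running density   4*L
EIIP      electron-ion interaction pseudopotential per site     L
BPB       class-conditional positional nucleotide frequencies   2*L
========  ====================================================  ==========

NPPS and BPB have fit/transform semantics: their frequency tables are
estimated on the *training* split only, so encoding held-out data never
touches held-out labels.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .data_io import SampleSet

NUCS = "ACGU"
NUC_INDEX = {n: i for i, n in enumerate(NUCS)}


# ---------------------------------------------------------------------------
# FeatureBlock container
# ---------------------------------------------------------------------------

@dataclass
class FeatureBlock:
    """A named numeric matrix (samples x features) with labeled columns."""

    name: str
    matrix: np.ndarray
    columns: list[str]
    sample_ids: list[str] = field(default_factory=list)
    #: for fused blocks: the source-block name of each column
    column_blocks: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.matrix.shape[1] != len(self.columns):
            raise ValueError(
                f"block {self.name!r}: {self.matrix.shape[1]} columns in the "
                f"matrix but {len(self.columns)} column labels"
            )
        if len(set(self.columns)) != len(self.columns):
            raise ValueError(f"block {self.name!r}: duplicate column labels")
        if self.sample_ids and len(self.sample_ids) != self.matrix.shape[0]:
            raise ValueError(f"block {self.name!r}: sample id / row mismatch")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(f"block {self.name!r}: non-finite values")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def prefixed_columns(self) -> list[str]:
        return [f"{self.name}_{c}" for c in self.columns]

    def subset_rows(self, indices) -> "FeatureBlock":
        ids = [self.sample_ids[i] for i in indices] if self.sample_ids else []
        return FeatureBlock(self.name, self.matrix[list(indices)],
                            list(self.columns), ids, self.column_blocks)

    def to_tsv(self, path: str | Path) -> None:
        ids = self.sample_ids or [str(i) for i in range(self.n_samples)]
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.prefixed_columns()) + "\n")
            for sid, row in zip(ids, self.matrix):
                fh.write(sid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, name: str) -> "FeatureBlock":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            ids, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                ids.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        prefix = f"{name}_"
        cols = [c[len(prefix):] if c.startswith(prefix) else c for c in header]
        return cls(name, np.array(rows), cols, ids)


def fuse_features(blocks: list[FeatureBlock],
                  name: str = "fused") -> FeatureBlock:
    """Horizontally concatenate feature blocks, prefixing column labels.

    All blocks must describe the same samples in the same row order.
    """
    if not blocks:
        raise ValueError("no blocks to fuse")
    n = blocks[0].n_samples
    ref_ids = blocks[0].sample_ids
    for b in blocks[1:]:
        if b.n_samples != n:
            raise ValueError(
                f"block {b.name!r} has {b.n_samples} rows, expected {n}"
            )
        if ref_ids and b.sample_ids and b.sample_ids != ref_ids:
            raise ValueError(f"block {b.name!r}: sample order differs")
    if len(blocks) == 1:
        return blocks[0]
    matrix = np.hstack([b.matrix for b in blocks])
    columns = [c for b in blocks for c in b.prefixed_columns()]
    col_blocks = [b.name for b in blocks for _ in b.columns]
    return FeatureBlock(name, matrix, columns, list(ref_ids), col_blocks)


def _seq_codes(data: SampleSet) -> np.ndarray:
    """(n_samples, L) integer codes, A=0 C=1 G=2 U=3."""
    lut = np.full(128, -1, dtype=np.int8)
    for n, i in NUC_INDEX.items():
        lut[ord(n)] = i
    arr = np.frombuffer(
        "".join(data.sequences).encode(), dtype=np.uint8
    ).reshape(len(data), data.seq_length)
    return lut[arr].astype(np.int64)


# ---------------------------------------------------------------------------
# CTD
# ---------------------------------------------------------------------------

def encode_ctd(data: SampleSet) -> FeatureBlock:
    """Composition / Transition / Distribution global descriptors.

    Composition: fraction of each nucleotide (4). Transition: for each of
    the 6 unordered distinct nucleotide pairs, the fraction of adjacent
    positions holding that pair in either order (6). Distribution: for each
    nucleotide, the relative positions (position / L) of its 1st,
    ceil(0.25n)-th, ceil(0.5n)-th, ceil(0.75n)-th and n-th occurrence among
    its n occurrences; five zeros if absent (20). Total 30 columns.
    """
    L = data.seq_length
    codes = _seq_codes(data)
    n_samp = len(data)

    comp = np.stack([(codes == i).mean(axis=1) for i in range(4)], axis=1)

    pairs = list(itertools.combinations(range(4), 2))
    left, right = codes[:, :-1], codes[:, 1:]
    trans = np.empty((n_samp, 6))
    for j, (a, b) in enumerate(pairs):
        hits = ((left == a) & (right == b)) | ((left == b) & (right == a))
        trans[:, j] = hits.sum(axis=1) / (L - 1)

    quantiles = (0.25, 0.5, 0.75)
    dist = np.zeros((n_samp, 20))
    for s in range(n_samp):
        for nuc in range(4):
            occ = np.flatnonzero(codes[s] == nuc) + 1  # 1-based positions
            if occ.size == 0:
                continue
            n = occ.size
            picks = [occ[0]] + [occ[math.ceil(q * n) - 1] for q in quantiles] \
                + [occ[-1]]
            dist[s, nuc * 5: nuc * 5 + 5] = np.array(picks) / L

    columns = [f"comp_{n}" for n in NUCS]
    columns += [f"trans_{NUCS[a]}{NUCS[b]}" for a, b in pairs]
    for n in NUCS:
        columns += [f"dist_{n}_{tag}" for tag in
                    ("first", "q25", "q50", "q75", "last")]
    matrix = np.hstack([comp, trans, dist])
    return FeatureBlock("CTD", matrix, columns, data.ids)


# ---------------------------------------------------------------------------
# PseKNC
# ---------------------------------------------------------------------------

def load_property_table(path: str | Path | None = None) -> dict:
    """Load the RNA dinucleotide physicochemical table (JSON)."""
    if path is None:
        ref = resources.files("m6age.data") / "rna_dinucleotide_properties.json"
        raw = json.loads(ref.read_text())
    else:
        raw = json.loads(Path(path).read_text())
    return raw


def standardized_property_matrix(table: dict | None = None) -> np.ndarray:
    """(6, 16) property matrix z-scored across the 16 dinucleotides.

    Standardization uses the population standard deviation, so each row has
    mean 0 and variance 1 exactly.
    """
    raw = table if table is not None else load_property_table()
    dinucs = ["".join(p) for p in itertools.product(NUCS, repeat=2)]
    mat = np.array([raw["values"][d] for d in dinucs]).T  # props x 16
    mean = mat.mean(axis=1, keepdims=True)
    std = mat.std(axis=1, keepdims=True)
    return (mat - mean) / std


@dataclass
class PseKNCParams:
    """Pseudo k-tuple nucleotide composition parameters.

    ``lam`` counts the sequence-order correlation tiers (must satisfy
    lam < L - 1 so every tier averages at least one dinucleotide pair);
    ``w`` weights the tier terms against the k-mer frequencies.
    """

    k: int = 3
    lam: int = 2
    w: float = 0.1
    property_table: dict | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.w <= 0:
            raise ValueError("weight factor w must be > 0")


def encode_pseknc(data: SampleSet, params: PseKNCParams | None = None) -> FeatureBlock:
    """Pseudo k-tuple nucleotide composition.

    The first 4^k components are normalized k-mer frequencies damped by the
    tier sum; the last lambda components are the weighted tier correlation
    factors theta_j, where theta_j averages the squared-difference
    correlation of standardized dinucleotide properties between dinucleotide
    pairs j apart. All 4^k + lambda components sum to 1.
    """
    params = params or PseKNCParams()
    L = data.seq_length
    if params.lam >= L - 1:
        raise ValueError(
            f"lambda={params.lam} too large for L={L}; need lambda < L-1"
        )
    P = standardized_property_matrix(params.property_table)  # (6, 16)
    codes = _seq_codes(data)
    n_samp = len(data)
    k = params.k

    # k-mer frequencies
    n_kmers = 4 ** k
    kmer_ids = np.zeros((n_samp, L - k + 1), dtype=np.int64)
    for off in range(k):
        kmer_ids = kmer_ids * 4 + codes[:, off: L - k + 1 + off]
    freqs = np.zeros((n_samp, n_kmers))
    for s in range(n_samp):
        counts = np.bincount(kmer_ids[s], minlength=n_kmers)
        freqs[s] = counts / counts.sum()

    # dinucleotide ids and per-sample property profiles
    di_ids = codes[:, :-1] * 4 + codes[:, 1:]          # (n, L-1)
    prop = P[:, di_ids]                                 # (6, n, L-1)

    thetas = np.zeros((n_samp, params.lam))
    for j in range(1, params.lam + 1):
        d = prop[:, :, :-j] - prop[:, :, j:]            # (6, n, L-1-j)
        thetas[:, j - 1] = (d ** 2).mean(axis=0).mean(axis=1)

    denom = 1.0 + params.w * thetas.sum(axis=1, keepdims=True)
    matrix = np.hstack([freqs / denom, params.w * thetas / denom])
    columns = ["".join(p) for p in itertools.product(NUCS, repeat=k)]
    columns += [f"theta_{j}" for j in range(1, params.lam + 1)]
    return FeatureBlock("PseKNC", matrix, columns, data.ids)


# ---------------------------------------------------------------------------
# NPS
# ---------------------------------------------------------------------------

@dataclass
class NPSParams:
    """Nucleotide pair spectrum: ordered pairs with 1..d_max intervening bases."""

    d_max: int = 3

    def __post_init__(self) -> None:
        if self.d_max < 1:
            raise ValueError("d_max must be >= 1")


def encode_nps(data: SampleSet, params: NPSParams | None = None) -> FeatureBlock:
    """k-spaced nucleotide pair frequencies, k = 1..d_max (16*d_max columns).

    A k-spaced pair n1{k}n2 occupies positions (i, i+k+1); its count is
    divided by the number of such position pairs, L-k-1.
    """
    params = params or NPSParams()
    L = data.seq_length
    if L < params.d_max + 2:
        raise ValueError(f"need L >= d_max + 2 (= {params.d_max + 2}), got {L}")
    codes = _seq_codes(data)
    n_samp = len(data)
    blocks, columns = [], []
    for k in range(1, params.d_max + 1):
        pair_ids = codes[:, : L - k - 1] * 4 + codes[:, k + 1:]
        freqs = np.zeros((n_samp, 16))
        for s in range(n_samp):
            freqs[s] = np.bincount(pair_ids[s], minlength=16) / (L - k - 1)
        blocks.append(freqs)
        columns += [f"k{k}_{a}{b}" for a in NUCS for b in NUCS]
    return FeatureBlock("NPS", np.hstack(blocks), columns, data.ids)


# ---------------------------------------------------------------------------
# NPPS
# ---------------------------------------------------------------------------

@dataclass
class NppsModel:
    """Positional frequency tables for the pair position-specificity encoder.

    ``Fs_*`` are (4, L) single-nucleotide positional frequencies; ``Fd_*``
    are (16, L-k-1) frequencies of the k-spaced pair starting at each
    position, estimated separately on positive and negative training data.
    """

    k: int
    L: int
    Fs_pos: np.ndarray
    Fs_neg: np.ndarray
    Fd_pos: np.ndarray
    Fd_neg: np.ndarray

    def to_dict(self) -> dict:
        return {
            "k": self.k, "L": self.L,
            "Fs_pos": self.Fs_pos.tolist(), "Fs_neg": self.Fs_neg.tolist(),
            "Fd_pos": self.Fd_pos.tolist(), "Fd_neg": self.Fd_neg.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NppsModel":
        return cls(d["k"], d["L"],
                   np.array(d["Fs_pos"]), np.array(d["Fs_neg"]),
                   np.array(d["Fd_pos"]), np.array(d["Fd_neg"]))


def _positional_freqs(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    L = codes.shape[1]
    Fs = np.stack([(codes == i).mean(axis=0) for i in range(4)])
    pair_ids = codes[:, : L - k - 1] * 4 + codes[:, k + 1:]
    Fd = np.stack([(pair_ids == i).mean(axis=0) for i in range(16)])
    return Fs, Fd


def fit_npps(train: SampleSet, k: int = 1) -> NppsModel:
    """Estimate NPPS frequency tables from a labeled training set.

    Both classes must be present; positives and negatives get separate
    tables, and held-out data can then be encoded without its labels.
    """
    L = train.seq_length
    if L <= k + 1:
        raise ValueError(f"need L > k + 1, got L={L}, k={k}")
    labels = train.labels
    if labels.min() == labels.max():
        raise ValueError("NPPS requires both classes in the training set")
    codes = _seq_codes(train)
    Fs_pos, Fd_pos = _positional_freqs(codes[labels == 1], k)
    Fs_neg, Fd_neg = _positional_freqs(codes[labels == 0], k)
    return NppsModel(k, L, Fs_pos, Fs_neg, Fd_pos, Fd_neg)


def encode_npps(data: SampleSet, model: NppsModel) -> FeatureBlock:
    """Position-specific conditional pair-probability contrast.

    For each position j = k+2..L (1-based) with nucleotides (n1, n2) at
    (j-k-1, j): p_j^+- = Fd^+-(n1 n2, j-k-1) / Fs^+-(n2, j), taken as 0 when
    the denominator is 0, and the feature is p_j = p_j^+ - p_j^-.
    Output width L-k-1.
    """
    if data.seq_length != model.L:
        raise ValueError(
            f"model fitted at L={model.L}, data has L={data.seq_length}"
        )
    k, L = model.k, model.L
    codes = _seq_codes(data)
    n1 = codes[:, : L - k - 1]
    n2 = codes[:, k + 1:]
    pair_ids = n1 * 4 + n2
    start = np.arange(L - k - 1)

    def _p(Fd: np.ndarray, Fs: np.ndarray) -> np.ndarray:
        num = Fd[pair_ids, start]                 # (n, L-k-1)
        den = Fs[n2, start + k + 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        return out

    matrix = _p(model.Fd_pos, model.Fs_pos) - _p(model.Fd_neg, model.Fs_neg)
    columns = [f"p{j}" for j in range(k + 2, L + 1)]
    return FeatureBlock(f"NPPS_xi{k}", matrix, columns, data.ids)


def fit_encode_npps_multi(train: SampleSet, data: SampleSet,
                          ks: tuple[int, ...] = (1, 2)) -> FeatureBlock:
    """Fit NPPS on ``train`` and encode ``data`` for each spacing in ``ks``."""
    blocks = [encode_npps(data, fit_npps(train, k)) for k in ks]
    matrix = np.hstack([b.matrix for b in blocks])
    columns = [f"xi{k}_{c}" for k, b in zip(ks, blocks) for c in b.columns]
    return FeatureBlock("NPPS", matrix, columns, data.ids)


# ---------------------------------------------------------------------------
# NCP-ND
# ---------------------------------------------------------------------------

# ring structure / hydrogen bond / functional group bits
NCP_CODES = {"A": (1, 1, 1), "U": (0, 1, 0), "C": (0, 0, 1), "G": (1, 0, 0)}


def encode_ncp_nd(data: SampleSet) -> FeatureBlock:
    """Nucleotide chemical properties plus running nucleotide density.

    Per position i: the three chemical-property bits of the nucleotide
    (purine/pyrimidine ring, strong/weak hydrogen bonding, amino/keto
    group) followed by its density, the count of that nucleotide among
    positions 1..i divided by i. Width 4*L, position-major.
    """
    L = data.seq_length
    codes = _seq_codes(data)
    bit_table = np.array([NCP_CODES[n] for n in NUCS], dtype=float)  # (4,3)
    bits = bit_table[codes]                                   # (n, L, 3)

    same = codes[:, :, None] == codes[:, None, :]             # (n, L, L)
    prefix = np.tril(np.ones((L, L)))                          # j<=i mask
    density = (same * prefix[None]).sum(axis=2) / np.arange(1, L + 1)

    matrix = np.concatenate([bits, density[:, :, None]], axis=2)
    matrix = matrix.reshape(len(data), 4 * L)
    columns = [f"pos{i + 1}_{tag}" for i in range(L)
               for tag in ("ring", "hbond", "func", "density")]
    return FeatureBlock("NCP_ND", matrix, columns, data.ids)


# ---------------------------------------------------------------------------
# EIIP
# ---------------------------------------------------------------------------

EIIP_VALUES = {"A": 0.1260, "C": 0.0806, "G": 0.1335, "U": 0.1340}


def encode_eiip(data: SampleSet) -> FeatureBlock:
    """Electron-ion interaction pseudopotential of each nucleotide (L columns)."""
    table = np.array([EIIP_VALUES[n] for n in NUCS])
    matrix = table[_seq_codes(data)]
    columns = [f"pos{i + 1}" for i in range(data.seq_length)]
    return FeatureBlock("EIIP", matrix, columns, data.ids)


# ---------------------------------------------------------------------------
# BPB
# ---------------------------------------------------------------------------

@dataclass
class BpbModel:
    """Bi-profile Bayes positional nucleotide frequencies, (4, L) per class."""

    L: int
    f_pos: np.ndarray
    f_neg: np.ndarray

    def to_dict(self) -> dict:
        return {"L": self.L, "f_pos": self.f_pos.tolist(),
                "f_neg": self.f_neg.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "BpbModel":
        return cls(d["L"], np.array(d["f_pos"]), np.array(d["f_neg"]))


def fit_bpb(train: SampleSet) -> BpbModel:
    labels = train.labels
    if labels.min() == labels.max():
        raise ValueError("BPB requires both classes in the training set")
    codes = _seq_codes(train)
    f_pos = np.stack([(codes[labels == 1] == i).mean(axis=0) for i in range(4)])
    f_neg = np.stack([(codes[labels == 0] == i).mean(axis=0) for i in range(4)])
    return BpbModel(train.seq_length, f_pos, f_neg)


def encode_bpb(data: SampleSet, model: BpbModel) -> FeatureBlock:
    """Interleaved positive/negative positional frequencies of the observed
    nucleotide at each position (2*L columns)."""
    if data.seq_length != model.L:
        raise ValueError(
            f"model fitted at L={model.L}, data has L={data.seq_length}"
        )
    codes = _seq_codes(data)
    pos = np.arange(model.L)
    fp = model.f_pos[codes, pos]
    fn = model.f_neg[codes, pos]
    matrix = np.empty((len(data), 2 * model.L))
    matrix[:, 0::2] = fp
    matrix[:, 1::2] = fn
    columns = [f"pos{i + 1}_{cls}" for i in range(model.L)
               for cls in ("pos", "neg")]
    return FeatureBlock("BPB", matrix, columns, data.ids)


# ---------------------------------------------------------------------------
# Registry used by the pipeline
# ---------------------------------------------------------------------------

SEQUENCE_ENCODER_TAGS = ("CTD", "PseKNC", "NPS", "NPPS", "NCP_ND", "EIIP", "BPB")


def encode_block(tag: str, data: SampleSet, train: SampleSet,
                 params: dict | None = None) -> FeatureBlock:
    """Encode ``data`` with the encoder named ``tag``.

    ``train`` supplies the labeled sequences for the class-conditional
    encoders (NPPS, BPB); the stateless encoders ignore it.
    """
    params = params or {}
    if tag == "CTD":
        return encode_ctd(data)
    if tag == "PseKNC":
        return encode_pseknc(data, PseKNCParams(**params))
    if tag == "NPS":
        return encode_nps(data, NPSParams(**params))
    if tag == "NPPS":
        ks = tuple(params.get("ks", (1, 2)))
        return fit_encode_npps_multi(train, data, ks)
    if tag == "NCP_ND":
        return encode_ncp_nd(data)
    if tag == "EIIP":
        return encode_eiip(data)
    if tag == "BPB":
        return encode_bpb(data, fit_bpb(train))
    raise ValueError(f"unknown encoder tag {tag!r}")
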