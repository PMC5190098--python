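"""Sequence-coupled conditional-probability tables and the difference encoding.

The encoding treats a (2*xi+1)-mer window centered on a candidate site as a
chain of nearest-neighbor dependencies pointing away from the center: the
residues immediately flanking the center (positions -1 and +1) follow
class-conditional *marginal* distributions, and every further position i
follows a *conditional* distribution given its neighbor one step closer to
the center, p(R_i | R_{i+1}) upstream and p(R_i | R_{i-1}) downstream.  Two
sets of tables are fitted by plain relative frequency — one on the positive
(true-site) windows, one on the negative windows — and a window is encoded
as the 2*xi-vector of positive-minus-negative probabilities looked up at the
residue pairs actually present in the window.  The dummy residue X takes
part as an ordinary 21st symbol, since terminal padding puts it inside
windows.

Feature order is -xi, ..., -1, +1, ..., +xi; with xi=10 this is the 20-D
vector fed to the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .peptides import ALPHABET, BenchmarkDataset, PeptideSample, ValidationError

N_SYMBOLS = len(ALPHABET)  # 21

_LUT = np.full(128, -1, dtype=np.int64)
for _i, _c in enumerate(ALPHABET):
    _LUT[ord(_c)] = _i

WindowLike = Union[str, PeptideSample]


def _as_window(sample: WindowLike) -> str:
    return sample.window if isinstance(sample, PeptideSample) else sample


def windows_to_codes(samples: Iterable[WindowLike], xi: int) -> np.ndarray:
    """Encode windows as an (n, 2*xi+1) integer matrix over the 21-alphabet."""
    windows = [_as_window(s) for s in samples]
    width = 2 * xi + 1
    for w in windows:
        if len(w) != width:
            raise ValidationError(
                f"window {w!r} has length {len(w)}, expected {width} for xi={xi}"
            )
    if not windows:
        return np.empty((0, width), dtype=np.int64)
    flat = np.frombuffer("".join(windows).encode("ascii"), dtype=np.uint8)
    codes = _LUT[flat].reshape(len(windows), width)
    if (codes < 0).any():
        bad = windows[int(np.argwhere(codes < 0)[0, 0])]
        raise ValidationError(f"window {bad!r} contains symbols outside the alphabet")
    return codes


def _parse_smoothing(smoothing) -> float:
    """Return the Laplace pseudo-count alpha (0 for mode 'none')."""
    if smoothing in (None, "none"):
        return 0.0
    if isinstance(smoothing, (int, float)) and not isinstance(smoothing, bool):
        alpha = float(smoothing)
    elif isinstance(smoothing, str) and smoothing.startswith("laplace"):
        inner = smoothing[len("laplace"):].strip("()")
        alpha = float(inner) if inner else 1.0
    else:
        raise ValidationError(f"unknown smoothing mode {smoothing!r}")
    if alpha < 0:
        raise ValidationError(f"smoothing pseudo-count must be >= 0, got {alpha}")
    return alpha


@dataclass(frozen=True)
class ClassTables:
    """Probability tables of one class (positive or negative).

    ``conditionals`` has shape (2*(xi-1), 21, 21) and is indexed by the
    position order -xi..-2, +2..+xi; ``conditionals[k, a, b]`` is
    p(residue a at that position | neighbor toward the center is b).  For a
    conditioning symbol b never observed at its slot, the whole column is 0
    (mode "none"); Laplace smoothing adds a pseudo-count to every pair.
    """

    xi: int
    alphabet: str
    marginal_minus1: np.ndarray  # (21,)
    marginal_plus1: np.ndarray   # (21,)
    conditionals: np.ndarray     # (2*(xi-1), 21, 21)

    @property
    def positions(self) -> list[int]:
        """Conditioned positions in table order: -xi..-2 then +2..+xi."""
        return list(range(-self.xi, -1)) + list(range(2, self.xi + 1))

    def equals(self, other: "ClassTables", atol: float = 0.0) -> bool:
        return (
            self.xi == other.xi
            and self.alphabet == other.alphabet
            and np.allclose(self.marginal_minus1, other.marginal_minus1, atol=atol, rtol=0)
            and np.allclose(self.marginal_plus1, other.marginal_plus1, atol=atol, rtol=0)
            and np.allclose(self.conditionals, other.conditionals, atol=atol, rtol=0)
        )


@dataclass(frozen=True)
class CouplingModel:
    """Positive- and negative-class tables for one target residue."""

    target: str
    positive: ClassTables
    negative: ClassTables

    def __post_init__(self) -> None:
        if self.positive.xi != self.negative.xi:
            raise ValidationError("positive and negative tables disagree on xi")
        if self.positive.alphabet != self.negative.alphabet:
            raise ValidationError("positive and negative tables disagree on alphabet")

    @property
    def xi(self) -> int:
        return self.positive.xi

    @property
    def n_features(self) -> int:
        return 2 * self.xi


def fit_class_tables(samples: Sequence[WindowLike], xi: int,
                     smoothing="none") -> ClassTables:
    """Fit the per-position marginal/conditional tables by relative frequency."""
    alpha = _parse_smoothing(smoothing)
    codes = windows_to_codes(samples, xi)
    n = codes.shape[0]
    if n == 0:
        raise ValidationError("cannot fit class tables on an empty sample list")

    def marginal(col: np.ndarray) -> np.ndarray:
        counts = np.bincount(col, minlength=N_SYMBOLS).astype(float) + alpha
        return counts / counts.sum()

    marginal_minus1 = marginal(codes[:, xi - 1])
    marginal_plus1 = marginal(codes[:, xi + 1])

    cond = np.zeros((2 * (xi - 1), N_SYMBOLS, N_SYMBOLS))
    slots = []
    for k in range(xi, 1, -1):          # positions -xi .. -2
        slots.append((xi - k, xi - k + 1))
    for k in range(2, xi + 1):          # positions +2 .. +xi
        slots.append((xi + k, xi + k - 1))
    for idx, (slot, neighbor_slot) in enumerate(slots):
        pair_counts = np.zeros((N_SYMBOLS, N_SYMBOLS))
        np.add.at(pair_counts, (codes[:, slot], codes[:, neighbor_slot]), 1.0)
        pair_counts += alpha
        col_totals = pair_counts.sum(axis=0)
        nonzero = col_totals > 0
        cond[idx, :, nonzero] = (pair_counts[:, nonzero] / col_totals[nonzero]).T
    return ClassTables(
        xi=xi, alphabet=ALPHABET,
        marginal_minus1=marginal_minus1, marginal_plus1=marginal_plus1,
        conditionals=cond,
    )


def fit_model(dataset: BenchmarkDataset, smoothing="none") -> CouplingModel:
    """Fit positive tables on the positive subset, negative on the negative."""
    return CouplingModel(
        target=dataset.target,
        positive=fit_class_tables(dataset.positives, dataset.xi, smoothing),
        negative=fit_class_tables(dataset.negatives, dataset.xi, smoothing),
    )


def _encode_codes(codes: np.ndarray, model: CouplingModel) -> np.ndarray:
    xi = model.xi
    n = codes.shape[0]
    out = np.empty((n, 2 * xi))
    pos_t, neg_t = model.positive, model.negative
    # columns 0..xi-2: positions -xi..-2 (conditional table index == column)
    for j in range(xi - 1):
        slot = j                      # window slot of position -(xi - j)
        a = codes[:, slot]
        b = codes[:, slot + 1]
        out[:, j] = pos_t.conditionals[j, a, b] - neg_t.conditionals[j, a, b]
    out[:, xi - 1] = (pos_t.marginal_minus1 - neg_t.marginal_minus1)[codes[:, xi - 1]]
    out[:, xi] = (pos_t.marginal_plus1 - neg_t.marginal_plus1)[codes[:, xi + 1]]
    # columns xi+1..2xi-1: positions +2..+xi (table index xi-1 .. 2xi-3)
    for j in range(xi - 1):
        slot = xi + 2 + j             # window slot of position +(2 + j)
        a = codes[:, slot]
        b = codes[:, slot - 1]
        out[:, xi + 1 + j] = (pos_t.conditionals[xi - 1 + j, a, b]
                              - neg_t.conditionals[xi - 1 + j, a, b])
    return out


def encode(sample: WindowLike, model: CouplingModel) -> np.ndarray:
    """Encode one window as its 2*xi difference feature vector."""
    codes = windows_to_codes([sample], model.xi)
    return _encode_codes(codes, model)[0]


def encode_windows(samples: Sequence[WindowLike], model: CouplingModel) -> np.ndarray:
    """Encode many windows; rows follow the input order."""
    codes = windows_to_codes(samples, model.xi)
    return _encode_codes(codes, model)


def encode_dataset(dataset: BenchmarkDataset,
                   model: CouplingModel) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (positives then negatives) and 1/0 label vector."""
    X = encode_windows(list(dataset.positives) + list(dataset.negatives), model)
    y = np.concatenate([
        np.ones(len(dataset.positives), dtype=int),
        np.zeros(len(dataset.negatives), dtype=int),
    ])
    return X, y


# ---------------------------------------------------------------------------
# Text serialization: exact write -> read round-trip ('%.17g' floats).
# ---------------------------------------------------------------------------

def _write_array(fh, name: str, arr: np.ndarray) -> None:
    fh.write(f"array {name} {' '.join(str(d) for d in arr.shape)}\n")
    for val in arr.ravel():
        fh.write("%.17g\n" % val)


def save_model(model: CouplingModel, path: str | Path, smoothing="none") -> None:
    """Write a coupling model to a structured text file."""
    with open(Path(path), "w") as fh:
        fh.write("hydsite-coupling-model 1\n")
        fh.write(f"target {model.target}\n")
        fh.write(f"xi {model.xi}\n")
        fh.write(f"alphabet {model.positive.alphabet}\n")
        fh.write(f"smoothing {smoothing}\n")
        for cls_name, tables in (("positive", model.positive), ("negative", model.negative)):
            fh.write(f"class {cls_name}\n")
            _write_array(fh, "marginal_minus1", tables.marginal_minus1)
            _write_array(fh, "marginal_plus1", tables.marginal_plus1)
            _write_array(fh, "conditionals", tables.conditionals)


def load_model(path: str | Path) -> CouplingModel:
    """Read a coupling model written by :func:`save_model`."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    it = iter(enumerate(lines, start=1))

    def next_line() -> tuple[int, str]:
        try:
            return next(it)
        except StopIteration:
            raise ValidationError(f"{path}: truncated model file")

    lineno, header = next_line()
    if not header.startswith("hydsite-coupling-model"):
        raise ValidationError(f"{path}:{lineno}: not a coupling-model file")
    meta: dict[str, str] = {}
    for key in ("target", "xi", "alphabet", "smoothing"):
        lineno, line = next_line()
        k, _, v = line.partition(" ")
        if k != key:
            raise ValidationError(f"{path}:{lineno}: expected key {key!r}, got {k!r}")
        meta[key] = v
    xi = int(meta["xi"])

    def read_array(expect_name: str) -> np.ndarray:
        lineno, line = next_line()
        parts = line.split()
        if parts[0] != "array" or parts[1] != expect_name:
            raise ValidationError(f"{path}:{lineno}: expected array {expect_name!r}")
        shape = tuple(int(d) for d in parts[2:])
        size = int(np.prod(shape))
        vals = np.empty(size)
        for i in range(size):
            _, v = next_line()
            vals[i] = float(v)
        return vals.reshape(shape)

    tables = {}
    for cls_name in ("positive", "negative"):
        lineno, line = next_line()
        if line != f"class {cls_name}":
            raise ValidationError(f"{path}:{lineno}: expected 'class {cls_name}'")
        tables[cls_name] = ClassTables(
            xi=xi, alphabet=meta["alphabet"],
            marginal_minus1=read_array("marginal_minus1"),
            marginal_plus1=read_array("marginal_plus1"),
            conditionals=read_array("conditionals"),
        )
    return CouplingModel(target=meta["target"], positive=tables["positive"],
                         negative=tables["negative"])


class SequenceCouplingEncoder(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer wrapping the difference encoding.

    fit(X, y) takes windows (strings or :class:`PeptideSample`) and binary
    labels (1 = true site) and learns the class-conditional tables;
    transform(X) maps windows to the 2*xi-dimensional feature matrix.

    Parameters
    ----------
    smoothing : "none" or "laplace(alpha)" or float
        Pseudo-count mode for unseen residue pairs.  The default leaves the
        probability of an unseen conditioning context at 0.
    """

    def __init__(self, smoothing="none"):
        self.smoothing = smoothing

    def fit(self, X: Sequence[WindowLike], y) -> "SequenceCouplingEncoder":
        windows = [_as_window(s) for s in X]
        y = np.asarray(y)
        if len(windows) != len(y):
            raise ValidationError("X and y have different lengths")
        if len(windows) == 0:
            raise ValidationError("cannot fit on an empty window list")
        width = len(windows[0])
        if width % 2 == 0:
            raise ValidationError("window length must be odd (2*xi + 1)")
        xi = width // 2
        centers = {w[xi] for w in windows}
        if len(centers) != 1:
            raise ValidationError(f"mixed center residues {sorted(centers)} in training windows")
        labels = set(np.unique(y).tolist())
        if not labels <= {0, 1} or labels != {0, 1}:
            raise ValidationError("y must contain both classes, encoded as 0/1")
        pos = [w for w, lab in zip(windows, y) if lab == 1]
        neg = [w for w, lab in zip(windows, y) if lab == 0]
        self.xi_ = xi
        self.target_ = next(iter(centers))
        self.model_ = CouplingModel(
            target=self.target_,
            positive=fit_class_tables(pos, xi, self.smoothing),
            negative=fit_class_tables(neg, xi, self.smoothing),
        )
        self.n_features_out_ = 2 * xi
        return self

    def transform(self, X: Sequence[WindowLike]) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise ValidationError("encoder is not fitted")
        return encode_windows(list(X), self.model_)
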