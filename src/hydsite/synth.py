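"""Synthetic annotated proteins with known class-specific neighbor coupling.

The generator emulates exactly the statistical structure the encoder
assumes: flanks of a candidate site are produced by a first-order Markov
chain running outward from the center (position -1 from a marginal, -2
conditioned on -1, and so on), with one chain per class.  Knobs:

* ``coupling_strength`` interpolates between a single shared set of tables
  (0: the two classes are indistinguishable) and independently sampled
  class-specific tables (1: strong signal).
* ``site_density`` is the fraction of planted target residues that are true
  sites.

Design notes (see docs/methods.md for the full rationale): the class tables
live on a small sub-alphabet of the 19 non-target residues (default 4
letters) and are doubly stochastic (Sinkhorn-balanced), with uniform +-1
marginals.  This keeps every conditioning context well sampled — so fitted
tables converge to the generator's at realistic benchmark sizes — and makes
the two classes differ only through nearest-neighbor coupling, never
through single-residue composition.  Site windows are planted with spacing
at least 2*xi+1 so windows never overlap.  None of this aims to mimic real
collagen biology; the generator targets the model's assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coupling import N_SYMBOLS, ClassTables, CouplingModel
from .peptides import (ALPHABET, AMINO_ACIDS, AnnotatedProtein, BenchmarkDataset,
                       PeptideSample, ProteinRecord, ValidationError, build_benchmark)


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one synthetic dataset."""

    target: str = "P"
    xi: int = 10
    n_proteins: int = 50
    length_range: tuple[int, int] = (80, 200)
    site_density: float = 0.5
    coupling_strength: float = 1.0
    background: dict[str, float] | None = None  # over the 20 standard residues
    seed: int = 0
    support_size: int = 4         # flank sub-alphabet size
    table_sharpness: float = 2.0  # spread of the log-normal table noise

    def __post_init__(self) -> None:
        if self.target not in AMINO_ACIDS:
            raise ValidationError(f"target must be a standard residue, got {self.target!r}")
        if self.xi < 1:
            raise ValidationError("xi must be >= 1")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValidationError("coupling_strength must be in [0, 1]")
        if not 0.0 <= self.site_density <= 1.0:
            raise ValidationError("site_density must be in [0, 1]")
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be >= 1")
        lo, hi = self.length_range
        if lo > hi or lo < 1:
            raise ValidationError(f"bad length_range {self.length_range}")
        if not 2 <= self.support_size <= 19:
            raise ValidationError("support_size must be in [2, 19]")
        if self.background is not None:
            bad = set(self.background) - set(AMINO_ACIDS)
            if bad:
                raise ValidationError(f"background contains non-standard letters {sorted(bad)}")
            total = sum(self.background.values())
            if not np.isclose(total, 1.0):
                raise ValidationError(f"background must sum to 1, sums to {total}")

    def background_vector(self) -> np.ndarray:
        """Background distribution over the 21-symbol alphabet (X gets 0)."""
        vec = np.zeros(N_SYMBOLS)
        if self.background is None:
            vec[: len(AMINO_ACIDS)] = 1.0 / len(AMINO_ACIDS)
        else:
            for letter, p in self.background.items():
                vec[ALPHABET.index(letter)] = p
        return vec


def _rngs(spec: GeneratorSpec) -> tuple[np.random.Generator, np.random.Generator]:
    """Independent streams for table sampling and sequence sampling, so
    generate_tables(spec) returns exactly the tables generate_proteins uses."""
    return (np.random.default_rng([spec.seed, 0]),
            np.random.default_rng([spec.seed, 1]))


def _sinkhorn(matrix: np.ndarray, n_iter: int = 200) -> np.ndarray:
    """Balance a positive matrix to doubly stochastic (rows and columns sum 1)."""
    m = matrix.copy()
    for _ in range(n_iter):
        m /= m.sum(axis=0, keepdims=True)
        m /= m.sum(axis=1, keepdims=True)
    return m / m.sum(axis=0, keepdims=True)


def _sample_table_set(rng: np.random.Generator, spec: GeneratorSpec,
                      support: np.ndarray) -> np.ndarray:
    """One full set of conditional tables, shape (2*(xi-1), 21, 21).

    Each table is a Sinkhorn-balanced log-normal random matrix on the
    support sub-alphabet; all other rows/columns are zero.
    """
    k = len(support)
    n_tables = 2 * (spec.xi - 1)
    out = np.zeros((max(n_tables, 0), N_SYMBOLS, N_SYMBOLS))
    for t in range(n_tables):
        core = _sinkhorn(np.exp(spec.table_sharpness * rng.standard_normal((k, k))))
        out[t][np.ix_(support, support)] = core
    return out


def _embed_marginal(support: np.ndarray) -> np.ndarray:
    vec = np.zeros(N_SYMBOLS)
    vec[support] = 1.0 / len(support)
    return vec


def flank_support(spec: GeneratorSpec) -> np.ndarray:
    """The sub-alphabet (global symbol codes) used for site flanks."""
    rng_tables, _ = _rngs(spec)
    non_target = np.array([i for i, c in enumerate(AMINO_ACIDS) if c != spec.target])
    return np.sort(rng_tables.choice(non_target, size=spec.support_size, replace=False))


def generate_tables(spec: GeneratorSpec) -> tuple[ClassTables, ClassTables]:
    """True positive- and negative-class tables for the given spec.

    At coupling_strength 0 the two classes share one table set; at 1 they
    are independent; intermediate values interpolate linearly entry-wise.
    """
    rng_tables, _ = _rngs(spec)
    non_target = np.array([i for i, c in enumerate(AMINO_ACIDS) if c != spec.target])
    support = np.sort(rng_tables.choice(non_target, size=spec.support_size, replace=False))
    base = _sample_table_set(rng_tables, spec, support)
    alt_pos = _sample_table_set(rng_tables, spec, support)
    alt_neg = _sample_table_set(rng_tables, spec, support)
    c = spec.coupling_strength
    marg = _embed_marginal(support)

    def build(alt: np.ndarray) -> ClassTables:
        return ClassTables(
            xi=spec.xi, alphabet=ALPHABET,
            marginal_minus1=marg.copy(), marginal_plus1=marg.copy(),
            conditionals=(1.0 - c) * base + c * alt,
        )

    return build(alt_pos), build(alt_neg)


def true_model(spec: GeneratorSpec) -> CouplingModel:
    """The generator's tables packaged as a :class:`CouplingModel`."""
    pos, neg = generate_tables(spec)
    return CouplingModel(target=spec.target, positive=pos, negative=neg)


def _sample_categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Vectorized draw: probs is (n, K) row-stochastic; returns (n,) codes."""
    cdf = np.cumsum(probs, axis=1)
    u = rng.random(probs.shape[0])
    return np.minimum((u[:, None] > cdf).sum(axis=1), probs.shape[1] - 1)


def _sample_window_codes(tables: ClassTables, n: int, target_code: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw n windows (integer codes) from one class's outward Markov chains."""
    xi = tables.xi
    codes = np.empty((n, 2 * xi + 1), dtype=np.int64)
    codes[:, xi] = target_code
    prev = _sample_categorical(rng, np.tile(tables.marginal_minus1, (n, 1)))
    codes[:, xi - 1] = prev
    for k in range(2, xi + 1):          # positions -2 .. -xi
        t_idx = xi - k                  # table order -xi..-2 -> index xi-k
        probs = tables.conditionals[t_idx, :, prev].reshape(n, N_SYMBOLS)
        prev = _sample_categorical(rng, probs)
        codes[:, xi - k] = prev
    prev = _sample_categorical(rng, np.tile(tables.marginal_plus1, (n, 1)))
    codes[:, xi + 1] = prev
    for k in range(2, xi + 1):          # positions +2 .. +xi -> table index xi-1 ..
        probs = tables.conditionals[xi - 1 + (k - 2), :, prev].reshape(n, N_SYMBOLS)
        prev = _sample_categorical(rng, probs)
        codes[:, xi + k] = prev
    return codes


def _codes_to_window(row: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in row)


def generate_windows(spec: GeneratorSpec, n_pos: int, n_neg: int,
                     rng: np.random.Generator | None = None) -> list[PeptideSample]:
    """Draw labeled windows directly from the class chains (no protein scaffold)."""
    pos_tables, neg_tables = generate_tables(spec)
    if rng is None:
        _, rng = _rngs(spec)
    target_code = ALPHABET.index(spec.target)
    samples = []
    for tables, n, label in ((pos_tables, n_pos, "positive"),
                             (neg_tables, n_neg, "negative")):
        codes = _sample_window_codes(tables, n, target_code, rng)
        for i in range(n):
            samples.append(PeptideSample(
                window=_codes_to_window(codes[i]), center=spec.target, label=label,
                source_id=f"synth_{label[:3]}_{i}", center_position=spec.xi + 1,
            ))
    return samples


def generate_proteins(spec: GeneratorSpec,
                      rng: np.random.Generator | None = None) -> list[AnnotatedProtein]:
    """Generate annotated proteins with planted, well-separated site windows.

    The backbone is drawn from the background distribution with the target
    residue excluded; candidate centers are planted at the background rate
    of the target with spacing >= 2*xi+1, labeled true sites with
    probability ``site_density``, and their full +-xi flanks are redrawn
    from the matching class chain.

    An explicit ``rng`` replaces only the sequence stream; the class tables
    still come deterministically from ``spec.seed``, so independent protein
    sets can be drawn from one underlying model.
    """
    lo, hi = spec.length_range
    width = 2 * spec.xi + 1
    if hi < width:
        raise ValidationError(
            f"length_range {spec.length_range} too small to host a {width}-mer window"
        )
    pos_tables, neg_tables = generate_tables(spec)
    if rng is None:
        _, rng = _rngs(spec)
    target_code = ALPHABET.index(spec.target)
    bg = spec.background_vector()
    p_center = bg[target_code] if bg[target_code] > 0 else 0.05
    gap = bg.copy()
    gap[target_code] = 0.0
    gap = gap / gap.sum()

    proteins = []
    for i in range(spec.n_proteins):
        length = int(rng.integers(max(lo, width), hi + 1))
        seq = _sample_categorical(rng, np.tile(gap, (length, 1)))
        centers = []
        pos = spec.xi
        while pos <= length - spec.xi - 1:
            if rng.random() < p_center:
                centers.append(pos)
                pos += width
            else:
                pos += 1
        sites = []
        for c in centers:
            positive = rng.random() < spec.site_density
            tables = pos_tables if positive else neg_tables
            window = _sample_window_codes(tables, 1, target_code, rng)[0]
            seq[c - spec.xi : c + spec.xi + 1] = window
            if positive:
                sites.append(c + 1)  # 1-based
        record = ProteinRecord(id=f"synth{i:04d}",
                               sequence="".join(ALPHABET[s] for s in seq))
        proteins.append(AnnotatedProtein(record, frozenset(sites)))
    return proteins


def generate_benchmark(spec: GeneratorSpec, n_pos: int | None = None,
                       n_neg: int | None = None) -> BenchmarkDataset:
    """A screened benchmark dataset under the spec's study conditions.

    With explicit per-class counts, windows are drawn directly from the
    class chains; otherwise proteins are generated and windows extracted by
    the standard sliding-window construction.
    """
    if (n_pos is None) != (n_neg is None):
        raise ValidationError("give both n_pos and n_neg, or neither")
    if n_pos is not None:
        samples = generate_windows(spec, n_pos, n_neg)
        # apply the standard screening (dedupe within subsets, drop conflicts)
        pos, neg, seen_pos, seen_neg = [], [], set(), set()
        for s in samples:
            subset, seen = (pos, seen_pos) if s.is_positive else (neg, seen_neg)
            if s.window not in seen:
                seen.add(s.window)
                subset.append(s)
        conflicts = seen_pos & seen_neg
        return BenchmarkDataset(
            target=spec.target, xi=spec.xi,
            positives=tuple(s for s in pos if s.window not in conflicts),
            negatives=tuple(s for s in neg if s.window not in conflicts),
        )
    return build_benchmark(generate_proteins(spec), spec.target, spec.xi)


def write_manifest(spec: GeneratorSpec, path) -> None:
    """Record the generator spec (and seed) next to generated data."""
    import json
    from pathlib import Path

    d = {f: getattr(spec, f) for f in spec.__dataclass_fields__}
    Path(path).write_text(json.dumps(d, indent=2, default=list) + "\n")
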