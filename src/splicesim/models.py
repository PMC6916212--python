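"""Generative models for gene structure and sequence composition.

This module packages every distribution the simulator draws from:

* a three-step Markov chain over codon positions (first position marginal,
  second position conditional on the first, third conditional on the first
  two) used to emit coding sequence codon by codon;
* a zero-order nucleotide chain for intron sequence;
* the empirical splice-site dinucleotide distribution (98% GT-AG, 1% GC-AG,
  1% anything else);
* four moment-matched length/count laws (exon length, intron length, exons
  per transcript, transcripts per gene) built as discretized log-normals
  recalibrated so the discretized law reproduces the target mean and
  standard deviation;
* a 61x61 row-stochastic codon transition matrix with zero diagonal (a
  substitution event always changes the codon);
* a truncated power-law indel length distribution.

Probability tables live in ``splicesim/data`` as TSV files and are
renormalized row-wise at load (printed tables carry two-decimal rounding).
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.stats import norm

__all__ = [
    "BASES",
    "SENSE_CODONS",
    "STOP_CODONS",
    "MIN_INTRON_LENGTH",
    "ConfigurationError",
    "CodonMarkovModel",
    "IntronNucleotideModel",
    "SpliceSiteDistribution",
    "LengthModel",
    "CodonSubstitutionMatrix",
    "IndelLengthModel",
    "EmpiricalModels",
    "build_default_models",
    "sample_length",
    "generate_codon",
    "sample_splice_sites",
]

BASES = ("A", "C", "T", "G")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product("ACTG", repeat=3)
    if "".join(c) not in STOP_CODONS
)

#: Shortest intron the generator will produce: room for both splice-site
#: dinucleotides plus an evolvable interior.
MIN_INTRON_LENGTH = 20

# Purine/pyrimidine classes for transition vs transversion.
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

_ROW_TOL = 1e-9


class ConfigurationError(ValueError):
    """A packaged or user-supplied model table failed validation."""


def _normalize_row(row: np.ndarray, what: str) -> np.ndarray:
    row = np.asarray(row, dtype=float)
    if np.any(row < 0):
        raise ConfigurationError(f"negative probability in {what}")
    total = row.sum()
    if not 0.5 < total < 1.5:
        raise ConfigurationError(
            f"row sum {total:.4f} of {what} is not close to 1")
    return row / total


def _read_table(name: str) -> dict[str, np.ndarray]:
    """Read a TSV with a header line ``key<TAB>A C T G`` into row vectors."""
    text = resources.files("splicesim.data").joinpath(name).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")[1:]
    if tuple(header) != BASES:
        raise ConfigurationError(f"{name}: column order must be A C T G")
    rows: dict[str, np.ndarray] = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        rows[parts[0]] = np.array([float(x) for x in parts[1:]])
    return rows


# ---------------------------------------------------------------------------
# Sequence-composition chains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonMarkovModel:
    """Codon-position Markov chains.

    ``p1`` is the marginal over {A,C,T,G} at the first codon position,
    ``p2[i]`` the conditional at position two given first base ``i`` and
    ``p3[4*i+j]`` the conditional at position three given first dinucleotide
    ``(i, j)``.  Stop codons are *not* excluded: the chain emits them at
    exactly the frequency the tables imply.
    """

    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray

    def __post_init__(self) -> None:
        if self.p1.shape != (4,) or self.p2.shape != (4, 4) \
                or self.p3.shape != (16, 4):
            raise ConfigurationError("codon chain tables have wrong shape")
        for name, arr in (("p1", self.p1[None, :]), ("p2", self.p2),
                          ("p3", self.p3)):
            sums = arr.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > _ROW_TOL):
                raise ConfigurationError(f"codon chain {name} rows != 1")

    def generate_codon(self, rng: np.random.Generator) -> str:
        i = rng.choice(4, p=self.p1)
        j = rng.choice(4, p=self.p2[i])
        k = rng.choice(4, p=self.p3[4 * i + j])
        return BASES[i] + BASES[j] + BASES[k]

    def generate_codons(self, n: int, rng: np.random.Generator) -> list[str]:
        """Vectorized draw of ``n`` independent codons."""
        if n == 0:
            return []
        u1, u2, u3 = rng.random((3, n))
        i = np.searchsorted(np.cumsum(self.p1), u1, side="right")
        i = np.minimum(i, 3)
        cum2 = np.cumsum(self.p2, axis=1)
        j = (u2[:, None] > cum2[i]).sum(axis=1)
        cum3 = np.cumsum(self.p3, axis=1)
        k = (u3[:, None] > cum3[4 * i + j]).sum(axis=1)
        letters = np.array(BASES)
        tri = np.stack([letters[i], letters[j], letters[k]], axis=1)
        return ["".join(t) for t in tri]

    def codon_frequencies(self) -> dict[str, float]:
        """Joint codon law implied by the three chains (includes stops)."""
        out = {}
        for i, a in enumerate(BASES):
            for j, b in enumerate(BASES):
                for k, c in enumerate(BASES):
                    out[a + b + c] = (
                        self.p1[i] * self.p2[i, j] * self.p3[4 * i + j, k])
        return out


@dataclass(frozen=True)
class IntronNucleotideModel:
    """Zero-order chain over {A,C,T,G} for intron sequence."""

    p0: np.ndarray

    def __post_init__(self) -> None:
        if self.p0.shape != (4,) or abs(self.p0.sum() - 1.0) > _ROW_TOL:
            raise ConfigurationError("intron nucleotide row does not sum to 1")

    def generate_sequence(self, n: int, rng: np.random.Generator) -> str:
        if n == 0:
            return ""
        idx = rng.choice(4, size=n, p=self.p0)
        return "".join(np.array(BASES)[idx])

    def substitute(self, base: str, rng: np.random.Generator) -> str:
        """Draw a base != ``base`` from ``p0`` restricted and renormalized."""
        i = _BASE_INDEX[base]
        p = self.p0.copy()
        p[i] = 0.0
        p /= p.sum()
        return BASES[rng.choice(4, p=p)]


@dataclass(frozen=True)
class SpliceSiteDistribution:
    """Donor/acceptor dinucleotide pair distribution.

    A category with donor/acceptor ``"*"`` stands for "any other pair": a
    draw from it returns a uniformly random dinucleotide pair that is
    neither GT-AG nor GC-AG.
    """

    categories: tuple[tuple[str, str, float], ...] = (
        ("GT", "AG", 0.98), ("GC", "AG", 0.01), ("*", "*", 0.01))

    def __post_init__(self) -> None:
        total = sum(p for _, _, p in self.categories)
        if abs(total - 1.0) > _ROW_TOL or any(
                p < 0 for _, _, p in self.categories):
            raise ConfigurationError("splice-site probabilities must sum to 1")

    def sample(self, rng: np.random.Generator) -> tuple[str, str]:
        probs = [p for _, _, p in self.categories]
        c = rng.choice(len(self.categories), p=probs)
        donor, acceptor, _ = self.categories[c]
        if donor != "*":
            return donor, acceptor
        named = {(d, a) for d, a, _ in self.categories if d != "*"}
        while True:
            pair = ("".join(rng.choice(list(BASES), size=2)),
                    "".join(rng.choice(list(BASES), size=2)))
            if pair not in named:
                return pair


# ---------------------------------------------------------------------------
# Length / count models
# ---------------------------------------------------------------------------

_LENGTH_KINDS = ("exon_length", "intron_length",
                 "exons_per_transcript", "transcripts_per_gene")


@dataclass(frozen=True)
class LengthModel:
    """Discretized log-normal length/count law, calibrated by its moments.

    The underlying continuous law is log-normal; draws are discretized by
    kind (counts: round, floor 1; exon lengths: nearest positive multiple
    of 3; intron lengths: round, floor ``MIN_INTRON_LENGTH``).  ``mu`` and
    ``sigma`` are chosen numerically so that the *discretized* law has mean
    ``target_mean`` and std ``target_std``.
    """

    kind: str
    target_mean: float
    target_std: float
    mu: float = field(default=math.nan)
    sigma: float = field(default=math.nan)

    def __post_init__(self) -> None:
        if self.kind not in _LENGTH_KINDS:
            raise ConfigurationError(f"unknown length kind {self.kind!r}")
        if self.target_mean <= 0 or self.target_std <= 0:
            raise ConfigurationError("length moments must be positive")
        if math.isnan(self.mu):
            mu, sigma = _calibrate_lognormal(
                self.kind, self.target_mean, self.target_std)
            object.__setattr__(self, "mu", mu)
            object.__setattr__(self, "sigma", sigma)

    # -- discretization ----------------------------------------------------
    def discretize(self, x: np.ndarray) -> np.ndarray:
        return _discretize(self.kind, x)

    def sample(self, rng: np.random.Generator) -> int:
        return int(self.sample_many(1, rng)[0])

    def sample_many(self, n: int, rng: np.random.Generator) -> np.ndarray:
        x = rng.lognormal(self.mu, self.sigma, size=n)
        return self.discretize(x)

    def truncated_sample(self, rng: np.random.Generator, low: int,
                         high: int) -> int:
        """Rejection-sample a value in ``[low, high]`` (inclusive)."""
        if low > high:
            raise ValueError("empty truncation interval")
        for _ in range(10_000):
            v = self.sample(rng)
            if low <= v <= high:
                return v
        return int(rng.integers(low, high + 1))

    def exact_moments(self) -> tuple[float, float]:
        """Mean and std of the discretized law, computed analytically."""
        return _discrete_moments(self.kind, self.mu, self.sigma)


def _discretize(kind: str, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if kind == "exon_length":
        return np.maximum(3, 3 * np.rint(x / 3.0)).astype(np.int64)
    if kind == "intron_length":
        return np.maximum(MIN_INTRON_LENGTH, np.rint(x)).astype(np.int64)
    return np.maximum(1, np.rint(x)).astype(np.int64)


def _discrete_moments(kind: str, mu: float, sigma: float
                      ) -> tuple[float, float]:
    if kind == "intron_length":
        # Clipping at MIN_INTRON_LENGTH handled in closed form; integer
        # rounding shifts these moments by <0.02% and is ignored.
        lo = MIN_INTRON_LENGTH
        z = (math.log(lo) - mu) / sigma
        f_lo = norm.cdf(z)
        m1 = math.exp(mu + sigma ** 2 / 2)
        m2 = math.exp(2 * mu + 2 * sigma ** 2)
        e1 = lo * f_lo + m1 * norm.sf(z - sigma)
        e2 = lo ** 2 * f_lo + m2 * norm.sf(z - 2 * sigma)
        var = max(e2 - e1 ** 2, 0.0)
        return e1, math.sqrt(var)
    if kind == "exon_length":
        step, floor_v = 3, 3
    else:
        step, floor_v = 1, 1
    # Support values floor_v, floor_v+step, ...; bin j covers
    # (v_j - step/2, v_j + step/2], first bin open below.
    kmax = int(math.exp(mu + 8.5 * sigma) / step) + 2
    kmax = min(max(kmax, 50), 3_000_000)
    v = floor_v + step * np.arange(kmax, dtype=float)
    upper = norm.cdf((np.log(v + step / 2.0) - mu) / sigma)
    p = np.diff(np.concatenate(([0.0], upper)))
    p[-1] += 1.0 - upper[-1]
    e1 = float(np.dot(p, v))
    e2 = float(np.dot(p, v * v))
    return e1, math.sqrt(max(e2 - e1 ** 2, 0.0))


def _calibrate_lognormal(kind: str, mean: float, std: float
                         ) -> tuple[float, float]:
    """Find (mu, sigma) so the discretized law matches (mean, std)."""
    s2 = math.log(1.0 + (std / mean) ** 2)
    x0 = np.array([math.log(mean) - s2 / 2, 0.5 * math.log(s2)])

    def resid(x):
        m, s = _discrete_moments(kind, x[0], math.exp(x[1]))
        return [m / mean - 1.0, s / std - 1.0]

    sol = optimize.root(resid, x0, method="hybr", tol=1e-12)
    mu, sigma = sol.x[0], math.exp(sol.x[1])
    m, s = _discrete_moments(kind, mu, sigma)
    if abs(m / mean - 1.0) > 0.02 or abs(s / std - 1.0) > 0.02:
        raise ConfigurationError(
            f"length-model calibration failed for {kind}: "
            f"got mean {m:.3f} std {s:.3f} for targets {mean}/{std}")
    return mu, sigma


# ---------------------------------------------------------------------------
# Codon substitution matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonSubstitutionMatrix:
    """Row-stochastic 61x61 codon transition matrix with zero diagonal.

    Rows give, for each sense codon, the probability that a substitution
    event turns it into each other sense codon.  A substitution event on a
    codon outside the 61 sense codons (a stop emitted by the unfiltered
    codon chain) draws uniformly over the sense codons.
    """

    probs: np.ndarray
    codons: tuple[str, ...] = SENSE_CODONS

    def __post_init__(self) -> None:
        n = len(self.codons)
        if self.probs.shape != (n, n):
            raise ConfigurationError("codon matrix has wrong shape")
        if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > _ROW_TOL):
            raise ConfigurationError("codon matrix rows must sum to 1")
        if np.any(np.diag(self.probs) != 0.0):
            raise ConfigurationError("codon matrix diagonal must be zero")
        object.__setattr__(
            self, "_index", {c: i for i, c in enumerate(self.codons)})
        object.__setattr__(self, "_cum", np.cumsum(self.probs, axis=1))

    def sample_target(self, codon: str, rng: np.random.Generator) -> str:
        idx = self._index.get(codon)
        if idx is None:  # stop codon: uniform over sense codons
            return self.codons[rng.integers(len(self.codons))]
        j = int(np.searchsorted(self._cum[idx], rng.random(), side="right"))
        return self.codons[min(j, len(self.codons) - 1)]


def _transition_count(a: str, b: str) -> tuple[int, int]:
    """(number of differing positions, number that are transitions)."""
    diff = ts = 0
    for x, y in zip(a, b):
        if x != y:
            diff += 1
            if {x, y} <= _PURINES or {x, y} <= _PYRIMIDINES:
                ts += 1
    return diff, ts


def build_codon_substitution_matrix(
        chain: CodonMarkovModel, kappa: float = 4.0,
        multi_hit: float = 0.003) -> CodonSubstitutionMatrix:
    """Construct a synthetic empirical-style codon transition matrix.

    This is a synthetic stand-in for a published empirical codon exchange
    matrix: transition weights are the target codon's frequency under the
    packaged codon chain, multiplied by ``kappa`` per transition-type
    nucleotide change and discounted by ``multi_hit`` per nucleotide change
    beyond the first.  Rows are normalized; the diagonal is zero.
    """
    freqs = chain.codon_frequencies()
    pi = np.array([freqs[c] for c in SENSE_CODONS])
    pi /= pi.sum()
    n = len(SENSE_CODONS)
    w = np.zeros((n, n))
    for i, a in enumerate(SENSE_CODONS):
        for j, b in enumerate(SENSE_CODONS):
            if i == j:
                continue
            d, ts = _transition_count(a, b)
            w[i, j] = pi[j] * (kappa ** ts) * (multi_hit ** (d - 1))
    w /= w.sum(axis=1, keepdims=True)
    return CodonSubstitutionMatrix(probs=w)


# ---------------------------------------------------------------------------
# Indel lengths
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndelLengthModel:
    """Truncated power-law indel length distribution.

    ``P(L = k) ∝ k**-alpha`` for ``k = 1..max_length`` — the classic
    empirical indel-length shape.  Lengths are in codons for exon indels
    and nucleotides for intron indels.
    """

    max_length: int = 10
    alpha: float = 1.7

    def __post_init__(self) -> None:
        if self.max_length < 1:
            raise ConfigurationError("indel max_length must be >= 1")
        k = np.arange(1, self.max_length + 1, dtype=float)
        w = k ** (-self.alpha)
        object.__setattr__(self, "probs", w / w.sum())
        object.__setattr__(self, "_cum", np.cumsum(self.probs))

    def sample(self, rng: np.random.Generator) -> int:
        j = int(np.searchsorted(self._cum, rng.random(), side="right"))
        return min(j, self.max_length - 1) + 1


# ---------------------------------------------------------------------------
# Bundle and module-level operations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmpiricalModels:
    """All generative models used by one simulation run."""

    codon_chain: CodonMarkovModel
    intron_chain: IntronNucleotideModel
    splice_sites: SpliceSiteDistribution
    exon_length: LengthModel
    intron_length: LengthModel
    exons_per_transcript: LengthModel
    transcripts_per_gene: LengthModel
    codon_matrix: CodonSubstitutionMatrix
    indel_length: IndelLengthModel


#: (mean, std) targets of the packaged length/count laws.
LENGTH_TARGETS = {
    "exons_per_transcript": (9.62, 8.54),
    "transcripts_per_gene": (1.45, 1.08),
    "exon_length": (170.36, 258.86),
    "intron_length": (3730.30, 20126.39),
}


def load_codon_chain() -> CodonMarkovModel:
    p1 = _normalize_row(_read_table("codon_markov_p1.tsv")["p1"], "p1")
    t2 = _read_table("codon_markov_p2.tsv")
    p2 = np.stack([_normalize_row(t2[b], f"p2[{b}]") for b in BASES])
    t3 = _read_table("codon_markov_p3.tsv")
    p3 = np.stack([
        _normalize_row(t3[a + b], f"p3[{a}{b}]")
        for a in BASES for b in BASES])
    return CodonMarkovModel(p1=p1, p2=p2, p3=p3)


def load_intron_chain() -> IntronNucleotideModel:
    p0 = _normalize_row(_read_table("intron_nucleotide.tsv")["p0"], "p0")
    return IntronNucleotideModel(p0=p0)


def load_splice_sites() -> SpliceSiteDistribution:
    text = resources.files("splicesim.data").joinpath(
        "splice_sites.tsv").read_text()
    lines = [ln.split("\t") for ln in text.splitlines()[1:] if ln.strip()]
    cats = tuple((d, a, float(p)) for d, a, p in lines)
    return SpliceSiteDistribution(categories=cats)


@functools.lru_cache(maxsize=1)
def build_default_models() -> EmpiricalModels:
    """Build the full packaged model set (deterministic; no sampling).

    Length models are calibrated numerically at construction; the result is
    cached, so repeated calls are cheap.
    """
    chain = load_codon_chain()
    lms = {k: LengthModel(kind=k, target_mean=m, target_std=s)
           for k, (m, s) in LENGTH_TARGETS.items()}
    return EmpiricalModels(
        codon_chain=chain,
        intron_chain=load_intron_chain(),
        splice_sites=load_splice_sites(),
        exon_length=lms["exon_length"],
        intron_length=lms["intron_length"],
        exons_per_transcript=lms["exons_per_transcript"],
        transcripts_per_gene=lms["transcripts_per_gene"],
        codon_matrix=build_codon_substitution_matrix(chain),
        indel_length=IndelLengthModel(),
    )


def sample_length(model: LengthModel, rng: np.random.Generator) -> int:
    """Draw one length/count respecting the model kind's constraint."""
    return model.sample(rng)


def generate_codon(model: CodonMarkovModel, rng: np.random.Generator) -> str:
    return model.generate_codon(rng)


def sample_splice_sites(dist: SpliceSiteDistribution,
                        rng: np.random.Generator) -> tuple[str, str]:
    return dist.sample(rng)
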