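"""Pseudo K-tuple nucleotide composition (PseKNC) encoding of aptamer sequences.

An aptamer is represented by the concatenation of its pseudo 2-tuple and pseudo
3-tuple composition vectors. Each vector has 4^K K-mer frequency components
followed by lambda sequence-order correlation factors theta_1..theta_lambda,
jointly normalized so the vector sums to one:

    d_u = f_u / (sum f + w * sum theta)            u <= 4^K
    d_u = w * theta_{u-4^K} / (sum f + w * sum theta)   otherwise

theta_j is the average squared physicochemical dissimilarity between K-tuples
j steps apart, over N per-tuple properties standardized across the 4^K tuples.
U is mapped to T before encoding so DNA and RNA aptamers share one table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .sequence_io import NucleotideSequence

#: Lexicographic tuple order (A < C < G < T); fixed so feature names are stable.
BASES = "ACGT"


def _ktuples(K: int) -> list[str]:
    return ["".join(p) for p in product(BASES, repeat=K)]


@dataclass(frozen=True)
class KTuplePropertyTable:
    """Per-K-tuple physicochemical property values.

    ``values[tuple]`` is a length-N array; after :func:`standardize_properties`
    each property has mean 0 and population variance 1 across the 4^K tuples.
    """

    K: int
    property_names: tuple[str, ...]
    values: dict[str, np.ndarray]

    def __post_init__(self):
        expected = _ktuples(self.K)
        missing = [t for t in expected if t not in self.values]
        if missing:
            raise ValidationError(f"property table missing K-tuples: {missing[:4]}...")
        n = len(self.property_names)
        for t, v in self.values.items():
            if np.asarray(v).shape != (n,):
                raise ValidationError(f"tuple {t!r} has {len(v)} values, expected {n}")

    @property
    def n_properties(self) -> int:
        return len(self.property_names)

    def as_matrix(self) -> np.ndarray:
        """4^K x N matrix in lexicographic tuple order."""
        return np.array([self.values[t] for t in _ktuples(self.K)], dtype=float)

    @classmethod
    def from_tsv(cls, path: str | Path, K: int) -> "KTuplePropertyTable":
        """Read ``tuple<TAB>prop1...propN`` with an optional ``#`` comment header."""
        lines = [ln for ln in Path(path).read_text().splitlines()
                 if ln.strip() and not ln.startswith("#")]
        header = lines[0].split("\t")
        names = tuple(header[1:])
        values = {}
        for ln in lines[1:]:
            parts = ln.split("\t")
            values[parts[0].upper()] = np.array([float(x) for x in parts[1:]])
        return cls(K, names, values)


def standardize_properties(table: KTuplePropertyTable) -> KTuplePropertyTable:
    """Center and scale each property to mean 0 / population sd 1 across the
    4^K tuples. A zero-variance property is uninformative and raises."""
    m = table.as_matrix()
    mean = m.mean(axis=0)
    sd = m.std(axis=0)  # population sd
    zero = np.flatnonzero(sd < 1e-12)
    if zero.size:
        bad = [table.property_names[i] for i in zero]
        raise ValidationError(f"zero-variance K-tuple properties: {bad}")
    std = (m - mean) / sd
    tuples = _ktuples(table.K)
    return KTuplePropertyTable(
        table.K, table.property_names, {t: std[i] for i, t in enumerate(tuples)}
    )


def load_default_table(K: int) -> KTuplePropertyTable:
    """Shipped property tables, standardized: 6 dinucleotide base-step helical
    parameters for K=2; a 12-property trinucleotide table for K=3 (a documented
    synthetic stand-in derived from the base-step parameters)."""
    name = {
        2: "dinucleotide_properties.tsv",
        3: "trinucleotide_properties.synthetic.tsv",
    }[K]
    with resources.as_file(resources.files("aptapair.data") / name) as path:
        return standardize_properties(KTuplePropertyTable.from_tsv(path, K))


@dataclass(frozen=True)
class PseKNCConfig:
    """K, correlation depth lambda, and the weight factor omega (default 0.5,
    the conventional PseKNC choice). lambda defaults to L_min - K over the
    training aptamer corpus and must not exceed L - K of any encoded sequence."""

    K: int
    lam: int
    omega: float = 0.5

    def __post_init__(self):
        if self.K not in (2, 3):
            raise ValidationError(f"K must be 2 or 3, got {self.K}")
        if self.lam < 0:
            raise ValidationError(f"lambda must be >= 0, got {self.lam}")
        if self.omega <= 0:
            raise ValidationError(f"omega must be > 0, got {self.omega}")


def _tuple_indices(seq: NucleotideSequence, K: int) -> np.ndarray:
    s = seq.dna
    if len(s) < K:
        raise ValidationError(f"sequence {seq.id!r} shorter than K={K}")
    codes = np.frombuffer(s.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int64)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    c = lut[codes]
    idx = np.zeros(len(s) - K + 1, dtype=np.int64)
    for k in range(K):
        idx = idx * 4 + c[k : len(s) - K + 1 + k]
    return idx


def ktuple_frequencies(seq: NucleotideSequence, K: int) -> np.ndarray:
    """Normalized overlapping K-tuple counts in lexicographic order; sums to 1."""
    idx = _tuple_indices(seq, K)
    counts = np.bincount(idx, minlength=4**K).astype(float)
    return counts / idx.size


def correlation_factors(
    seq: NucleotideSequence, table: KTuplePropertyTable, lam: int
) -> np.ndarray:
    """theta_j for j=1..lambda: the mean over positions of the mean squared
    difference of the standardized property values between the K-tuples at
    positions i and i+j. Requires lambda <= L - K."""
    K = table.K
    L = len(seq)
    if lam > L - K:
        raise ValidationError(
            f"lambda={lam} exceeds L-K={L - K} for sequence {seq.id!r}"
        )
    H = table.as_matrix()[_tuple_indices(seq, K)]  # (L-K+1, N)
    theta = np.empty(lam)
    for j in range(1, lam + 1):
        d = H[:-j] - H[j:]
        theta[j - 1] = np.mean(d * d)  # mean over both positions and properties
    return theta


def pseknc_vector(
    seq: NucleotideSequence, table: KTuplePropertyTable, config: PseKNCConfig
) -> tuple[np.ndarray, list[str]]:
    """The (4^K + lambda)-dimensional pseudo composition vector with names."""
    f = ktuple_frequencies(seq, config.K)
    theta = correlation_factors(seq, table, config.lam)
    denom = f.sum() + config.omega * theta.sum()
    values = np.concatenate([f, config.omega * theta]) / denom
    names = [f"pse{config.K}_{t}" for t in _ktuples(config.K)] + [
        f"pse{config.K}_theta{j}" for j in range(1, config.lam + 1)
    ]
    return values, names


def encode_aptamer(
    seq: NucleotideSequence,
    tables: dict[int, KTuplePropertyTable] | None = None,
    configs: dict[int, PseKNCConfig] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Concatenated [PseKNC(K=2) | PseKNC(K=3)] block.

    Defaults: shipped property tables; lambda_2 = 6 and lambda_3 = 5 (the
    benchmark configuration, minimum aptamer length 8), giving 91 features.
    """
    if tables is None:
        tables = {2: load_default_table(2), 3: load_default_table(3)}
    if configs is None:
        configs = {2: PseKNCConfig(2, 6), 3: PseKNCConfig(3, 5)}
    values, names = [], []
    for K in (2, 3):
        v, n = pseknc_vector(seq, tables[K], configs[K])
        values.append(v)
        names.extend(n)
    return np.concatenate(values), names
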