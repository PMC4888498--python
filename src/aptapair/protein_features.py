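"""Protein feature encoders: DCT hydropathy spectra, bi-gram PSSM, disorder descriptors.

A protein is represented by 563 features in three blocks:

* 104 DCT features — the first 52 coefficients of the orthonormal DCT-II of the
  per-residue hydrophobicity signal, and the same for hydrophilicity. Low-frequency
  coefficients summarize the periodicity of hydropathy along the chain.
* 400 bi-gram PSSM features — B[m, n] = sum_i P[i, m] * P[i+1, n], transition-like
  products of consecutive-position PSSM entries, flattened row-major.
* 59 disorder features — autocovariance of the per-residue disorder track at lags
  1..51 plus eight run-length summaries (mean, sd, segment counts and extremal
  segment lengths above/below a disorder threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.fft import dct as _scipy_dct
from scipy.special import expit

from .errors import DimensionError, ValidationError
from .sequence_io import AMINO_ACIDS, DisorderTrack, PSSMProfile, ProteinSequence


@dataclass(frozen=True)
class HydropathyScale:
    """An amino-acid -> real index, standardized to mean 0 / population sd 1
    over the 20 standard residues. Letters outside the map (permissive B/Z/X/U/O)
    contribute 0, i.e. the scale mean."""

    name: str
    values: dict[str, float]

    def __post_init__(self):
        missing = [a for a in AMINO_ACIDS if a not in self.values]
        if missing:
            raise ValidationError(f"scale {self.name!r} missing residues {missing}")

    def standardized(self) -> "HydropathyScale":
        v = np.array([self.values[a] for a in AMINO_ACIDS])
        sd = v.std()
        if sd < 1e-12:
            raise ValidationError(f"scale {self.name!r} has zero variance")
        std = (v - v.mean()) / sd
        return HydropathyScale(self.name, dict(zip(AMINO_ACIDS, std)))

    def signal(self, protein: ProteinSequence) -> np.ndarray:
        return np.array([self.values.get(a, 0.0) for a in protein.residues])


def load_default_scales() -> dict[str, HydropathyScale]:
    """Kyte-Doolittle hydrophobicity and Hopp-Woods hydrophilicity, standardized."""
    path = resources.files("aptapair.data") / "hydropathy_scales.tsv"
    lines = [ln for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    names = lines[0].split("\t")[1:]
    raw: dict[str, dict[str, float]] = {n: {} for n in names}
    for ln in lines[1:]:
        parts = ln.split("\t")
        for n, x in zip(names, parts[1:]):
            raw[n][parts[0]] = float(x)
    return {n: HydropathyScale(n, raw[n]).standardized() for n in names}


def load_scales_tsv(path: str | Path) -> dict[str, HydropathyScale]:
    """User-supplied replacement scales, same TSV layout as the shipped file."""
    lines = [ln for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    names = lines[0].split("\t")[1:]
    raw: dict[str, dict[str, float]] = {n: {} for n in names}
    for ln in lines[1:]:
        parts = ln.split("\t")
        for n, x in zip(names, parts[1:]):
            raw[n][parts[0].upper()] = float(x)
    return {n: HydropathyScale(n, raw[n]).standardized() for n in names}


@dataclass(frozen=True)
class ProteinFeatureConfig:
    """Knobs for the three encoders.

    n_dct: retained low-frequency DCT coefficients per scale (52 = the benchmark
    minimum protein length). pssm_normalize: 'sigmoid' squashes log-odds through
    1/(1+e^-x) before the bi-gram products; 'none' uses raw scores. max_lag:
    autocovariance depth (51 = benchmark minimum protein length - 1).
    disorder_threshold: scores >= threshold count as disordered. pad_short
    zero-pads proteins shorter than the DCT/lag requirements instead of erroring.
    """

    n_dct: int = 52
    pssm_normalize: str = "sigmoid"
    max_lag: int = 51
    disorder_threshold: float = 0.5
    pad_short: bool = False

    def __post_init__(self):
        if self.pssm_normalize not in ("sigmoid", "none"):
            raise ValidationError(
                f"pssm_normalize must be 'sigmoid' or 'none', got {self.pssm_normalize!r}"
            )


def dct_features(
    protein: ProteinSequence,
    scale: HydropathyScale,
    n_components: int = 52,
    pad_short: bool = False,
) -> np.ndarray:
    """First ``n_components`` coefficients of the orthonormal DCT-II of the
    hydropathy signal:

        G(k) = a(k) * sum_n H(p_n) cos[(2n+1) k pi / (2L)]

    with a(0) = sqrt(1/L) and a(k>0) = sqrt(2/L), so the full transform is
    energy-preserving (Parseval).
    """
    x = scale.signal(protein)
    if x.size < n_components:
        if not pad_short:
            raise DimensionError(
                f"protein {protein.id!r} has L={x.size} < {n_components} DCT "
                "components; enable pad_short to zero-pad"
            )
        x = np.pad(x, (0, n_components - x.size))
    return _scipy_dct(x, type=2, norm="ortho")[:n_components]


def bigram_pssm_features(
    profile: PSSMProfile, normalize: str = "sigmoid"
) -> np.ndarray:
    """400 bi-gram transition features B[m, n] = sum_i P[i, m] P[i+1, n],
    flattened in order B[1,1]..B[1,20], B[2,1]..B[20,20].

    ``normalize='sigmoid'`` maps each log-odds entry through 1/(1+e^-x) first,
    keeping the products on a stable (0,1) scale; ``'none'`` uses raw scores.
    The zero-matrix homolog-free fallback yields 400 zeros under 'none' — under
    'sigmoid' a zero matrix is detected and also mapped to 400 zeros, so the
    fallback stays a recognizable null signal in both modes.
    """
    M = profile.matrix
    if M.shape[0] < 2:
        raise DimensionError(
            f"bi-gram features need L >= 2, got L={M.shape[0]} for {profile.protein_id!r}"
        )
    if normalize == "sigmoid":
        if not M.any():
            return np.zeros(400)
        M = expit(M)
    elif normalize != "none":
        raise ValidationError(f"unknown PSSM normalization {normalize!r}")
    B = M[:-1].T @ M[1:]
    return B.reshape(400)


def disorder_autocovariance(track: DisorderTrack, max_lag: int = 51) -> np.ndarray:
    """AC_lag = (1/(L-lag)) * sum_i (d_i - dbar)(d_{i+lag} - dbar) for
    lag = 1..max_lag, with dbar the global track mean. Requires L > max_lag."""
    d = track.scores
    L = d.size
    if L <= max_lag:
        raise DimensionError(
            f"autocovariance needs L > max_lag={max_lag}, got L={L} "
            f"for {track.protein_id!r}"
        )
    centered = d - d.mean()
    ac = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        ac[lag - 1] = np.dot(centered[:-lag], centered[lag:]) / (L - lag)
    return ac


def _runs(mask: np.ndarray) -> list[int]:
    """Lengths of maximal runs of True."""
    lengths, n = [], 0
    for m in mask:
        if m:
            n += 1
        elif n:
            lengths.append(n)
            n = 0
    if n:
        lengths.append(n)
    return lengths


def disorder_segment_features(track: DisorderTrack, threshold: float = 0.5) -> np.ndarray:
    """Eight run-length summaries of the disorder track: mean, population sd,
    number of disorder / non-disorder segments, and min/max lengths of each
    segment class. A disorder segment is a maximal run of scores >= threshold;
    an absent segment class reports min = max = 0 (explicit sentinel)."""
    d = track.scores
    mask = d >= threshold
    dis = _runs(mask)
    non = _runs(~mask)
    def ext(lengths):
        return (min(lengths), max(lengths)) if lengths else (0, 0)
    dmin, dmax = ext(dis)
    nmin, nmax = ext(non)
    return np.array([
        d.mean(), d.std(),  # population sd, matching the AC normalization style
        len(dis), len(non), dmin, dmax, nmin, nmax,
    ], dtype=float)


DISORDER_SUMMARY_NAMES = [
    "dis_mean", "dis_sd", "n_disorder_segments", "n_nondisorder_segments",
    "min_disorder_len", "max_disorder_len", "min_nondisorder_len", "max_nondisorder_len",
]


def disorder_features(track: DisorderTrack, config: ProteinFeatureConfig) -> np.ndarray:
    """51 autocovariance lags + 8 summaries = 59 disorder features."""
    return np.concatenate([
        disorder_autocovariance(track, config.max_lag),
        disorder_segment_features(track, config.disorder_threshold),
    ])


def encode_protein(
    protein: ProteinSequence,
    profile: PSSMProfile,
    track: DisorderTrack,
    scales: dict[str, HydropathyScale] | None = None,
    config: ProteinFeatureConfig | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Concatenated [DCT(104) | bi-gram(400) | disorder(59)] block with names."""
    if scales is None:
        scales = load_default_scales()
    if config is None:
        config = ProteinFeatureConfig()
    if len(profile) != len(protein):
        raise DimensionError(
            f"PSSM rows ({len(profile)}) != protein length ({len(protein)}) "
            f"for {protein.id!r}"
        )
    if len(track) != len(protein):
        raise DimensionError(
            f"disorder track length ({len(track)}) != protein length "
            f"({len(protein)}) for {protein.id!r}"
        )
    phob = dct_features(protein, scales["hydrophobicity"], config.n_dct, config.pad_short)
    phil = dct_features(protein, scales["hydrophilicity"], config.n_dct, config.pad_short)
    bigram = bigram_pssm_features(profile, config.pssm_normalize)
    dis = disorder_features(track, config)
    values = np.concatenate([phob, phil, bigram, dis])
    names = (
        [f"dct_phob_{k}" for k in range(config.n_dct)]
        + [f"dct_phil_{k}" for k in range(config.n_dct)]
        + [f"bg_{a}{b}" for a in profile.column_order for b in profile.column_order]
        + [f"ac_{lag}" for lag in range(1, config.max_lag + 1)]
        + DISORDER_SUMMARY_NAMES
    )
    return values, names
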