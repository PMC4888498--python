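"""Synthetic aptamer-protein corpora with a tunable planted class signal.

The generator emulates the four input kinds the pipeline consumes — aptamer and
protein FASTA, PSI-BLAST-style PSSM profiles, per-residue disorder tracks, and a
labelled pair table — so every downstream module is testable without external
tools. Interacting (positive) pairs differ from background in four channels
simultaneously, each scaled by ``effect_size``:

* aptamer dinucleotide composition (a first-order Markov bias toward CG/GC steps),
* PSSM column means (shifts on a fixed hydrophobic-vs-charged column pattern),
* disorder segment structure (longer, more prevalent disordered runs),

so ablations over feature families can be exercised qualitatively. At
``effect_size=0`` positives and negatives are identically distributed; all
output is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ValidationError
from .sequence_io import (
    AMINO_ACIDS,
    PSSM_COLUMN_ORDER,
    DisorderTrack,
    InteractionPair,
    NucleotideSequence,
    PairDataset,
    ProteinSequence,
    PSSMProfile,
    read_disorder_track,
    read_fasta,
    read_pair_table,
    read_pssm,
    write_disorder_track,
    write_fasta,
    write_pair_table,
    write_pssm_ascii,
)

#: Transition bias pattern (rows/cols in A,C,G,T order): positives are pushed
#: toward CG/GC steps and away from AT/TA steps.
_APTAMER_BIAS = np.zeros((4, 4))
_APTAMER_BIAS[1, 2] = _APTAMER_BIAS[2, 1] = 1.0   # C->G, G->C
_APTAMER_BIAS[0, 3] = _APTAMER_BIAS[3, 0] = -1.0  # A->T, T->A

#: PSSM column shift pattern: up on hydrophobic I/L/V/F, down on charged D/E/K/R.
_PSSM_PATTERN = np.zeros(20)
for _aa in "ILVF":
    _PSSM_PATTERN[PSSM_COLUMN_ORDER.index(_aa)] = 1.0
for _aa in "DEKR":
    _PSSM_PATTERN[PSSM_COLUMN_ORDER.index(_aa)] = -1.0


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for a synthetic corpus.

    Defaults mirror a small 1:3-imbalanced benchmark: n_pos=50, n_neg=150,
    aptamers of length 8-40 (minimum 8 so the default PseKNC lags are 6 and 5),
    proteins of length 52-120 (minimum 52 so all 52 DCT components and 51
    autocovariance lags are defined). ``effect_size`` >= 0 scales the planted
    class separation; 0 means identically distributed classes.
    """

    n_pos: int = 50
    n_neg: int = 150
    aptamer_length_range: tuple[int, int] = (8, 40)
    protein_length_range: tuple[int, int] = (52, 120)
    effect_size: float = 1.0
    zero_pssm_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValidationError("n_pos and n_neg must both be >= 1")
        if self.aptamer_length_range[0] < 4 or self.aptamer_length_range[0] > self.aptamer_length_range[1]:
            raise ValidationError(f"bad aptamer length range {self.aptamer_length_range}")
        if self.protein_length_range[0] < 52 or self.protein_length_range[0] > self.protein_length_range[1]:
            raise ValidationError(
                f"protein minimum length must be >= 52, got {self.protein_length_range}"
            )
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if not 0.0 <= self.zero_pssm_fraction < 1.0:
            raise ValidationError("zero_pssm_fraction must be in [0, 1)")


@dataclass
class SyntheticCorpus:
    dataset: PairDataset
    pssms: dict[str, PSSMProfile]
    tracks: dict[str, DisorderTrack]
    config: FixtureConfig


def _sample_aptamer(rng, length: int, bias: float, rna: bool) -> str:
    """First-order Markov chain over ACGT; ``bias`` tilts the transition logits."""
    logits = bias * _APTAMER_BIAS
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    states = np.empty(length, dtype=int)
    states[0] = rng.integers(4)
    for i in range(1, length):
        states[i] = rng.choice(4, p=probs[states[i - 1]])
    letters = "ACGU" if rna else "ACGT"
    return "".join(letters[s] for s in states)


def _sample_disorder(rng, length: int, effect: float, positive: bool) -> np.ndarray:
    """Two-state (ordered/disordered) Markov chain; positives dwell longer in the
    disordered state. Scores: disordered ~ N(0.8, 0.1), ordered ~ N(0.2, 0.1),
    clipped to [0, 1]."""
    shift = 0.08 * np.tanh(effect / 2.0) if positive else 0.0
    stay_dis = 0.90 + shift
    stay_ord = 0.90 - shift
    start_dis = 0.30 + (0.2 * np.tanh(effect / 2.0) if positive else 0.0)
    state = rng.random() < start_dis
    scores = np.empty(length)
    for i in range(length):
        mu = 0.8 if state else 0.2
        scores[i] = np.clip(rng.normal(mu, 0.1), 0.0, 1.0)
        stay = stay_dis if state else stay_ord
        if rng.random() >= stay:
            state = not state
    return scores


def generate_corpus(cfg: FixtureConfig | None = None) -> SyntheticCorpus:
    """Draw a full corpus: one aptamer and one protein per pair, with PSSM and
    disorder tracks for every protein. Deterministic given ``cfg.seed``."""
    if cfg is None:
        cfg = FixtureConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_pos + cfg.n_neg
    labels = np.array([1] * cfg.n_pos + [0] * cfg.n_neg)
    labels = rng.permutation(labels)

    aptamers: dict[str, NucleotideSequence] = {}
    proteins: dict[str, ProteinSequence] = {}
    pssms: dict[str, PSSMProfile] = {}
    tracks: dict[str, DisorderTrack] = {}
    pairs: list[InteractionPair] = []

    alo, ahi = cfg.aptamer_length_range
    plo, phi = cfg.protein_length_range
    aa = np.array(list(AMINO_ACIDS))

    for i in range(n):
        positive = labels[i] == 1
        aid, pid = f"apt{i:04d}", f"prot{i:04d}"

        # pin the first pair to the configured minimum lengths so corpus-derived
        # encoder parameters (PseKNC lags) are fixed by the config, not sampling
        alen = alo if i == 0 else int(rng.integers(alo, ahi + 1))
        bias = 0.7 * cfg.effect_size if positive else 0.0
        rna = bool(rng.random() < 0.5)
        aptamers[aid] = NucleotideSequence(aid, _sample_aptamer(rng, alen, bias, rna))

        plen = plo if i == 0 else int(rng.integers(plo, phi + 1))
        proteins[pid] = ProteinSequence(pid, "".join(rng.choice(aa, size=plen)))

        base = rng.normal(0.0, 4.0, size=(plen, 20))
        if positive:
            base = base + 1.2 * cfg.effect_size * _PSSM_PATTERN
        matrix = np.clip(np.rint(base), -10, 10)
        if rng.random() < cfg.zero_pssm_fraction:
            matrix = np.zeros((plen, 20))  # homolog-free protein
        pssms[pid] = PSSMProfile(pid, matrix)

        tracks[pid] = DisorderTrack(pid, _sample_disorder(rng, plen, cfg.effect_size, positive))
        pairs.append(InteractionPair(aid, pid, int(labels[i])))

    dataset = PairDataset(pairs, aptamers, proteins)
    return SyntheticCorpus(dataset, pssms, tracks, cfg)


def write_fixture(corpus: SyntheticCorpus, out_dir: str | Path) -> Path:
    """Write the corpus in the dialects ``sequence_io`` reads: two FASTA files,
    a pair TSV, one PSI-BLAST ASCII PSSM and one disorder track per protein,
    plus a manifest JSON with the config and per-file checksums."""
    out = Path(out_dir)
    (out / "pssm").mkdir(parents=True, exist_ok=True)
    (out / "disorder").mkdir(parents=True, exist_ok=True)
    ds = corpus.dataset
    write_fasta(ds.aptamers.values(), out / "aptamers.fasta")
    write_fasta(ds.proteins.values(), out / "proteins.fasta")
    write_pair_table(ds, out / "pairs.tsv")
    for pid in ds.proteins:
        write_pssm_ascii(corpus.pssms[pid], out / "pssm" / f"{pid}.pssm")
        write_disorder_track(corpus.tracks[pid], out / "disorder" / f"{pid}.txt")

    checksums = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            checksums[str(path.relative_to(out))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    manifest = {"config": asdict(corpus.config), "checksums": checksums}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def load_fixture(fixture_dir: str | Path) -> SyntheticCorpus:
    """Re-read a written fixture through the standard readers (round-trip)."""
    d = Path(fixture_dir)
    aptamers = {s.id: s for s in read_fasta(d / "aptamers.fasta", "nucleotide")}
    proteins = {s.id: s for s in read_fasta(d / "proteins.fasta", "protein")}
    dataset = read_pair_table(d / "pairs.tsv", aptamers, proteins)
    pssms = {pid: read_pssm(d / "pssm" / f"{pid}.pssm", pid) for pid in proteins}
    tracks = {
        pid: read_disorder_track(d / "disorder" / f"{pid}.txt", pid) for pid in proteins
    }
    manifest = json.loads((d / "manifest.json").read_text())
    cfg = FixtureConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in manifest["config"].items()
    })
    return SyntheticCorpus(dataset, pssms, tracks, cfg)
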