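"""Assemble the pair-level feature matrix from a dataset and its protein tracks.

Each pair's vector is [aptamer PseKNC block | protein block]; under the benchmark
length configuration (minimum aptamer length 8, minimum protein length 52) this is
91 + 563 = 654 features. Protein encodings are computed once per protein and
re-used across pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .aptamer_features import (
    KTuplePropertyTable,
    PseKNCConfig,
    encode_aptamer,
    load_default_table,
)
from .errors import ValidationError
from .protein_features import (
    HydropathyScale,
    ProteinFeatureConfig,
    PSSMProfile,
    encode_protein,
    load_default_scales,
)
from .sequence_io import DisorderTrack, PairDataset, corpus_min_length

logger = logging.getLogger(__name__)


@dataclass
class EncoderConfig:
    """Everything needed to encode a dataset reproducibly.

    lambda_2 / lambda_3 default to L_min - K over the aptamer corpus being
    encoded (None = derive at encode time); omega is the PseKNC weight factor.
    """

    lambda_2: int | None = None
    lambda_3: int | None = None
    omega: float = 0.5
    protein: ProteinFeatureConfig = field(default_factory=ProteinFeatureConfig)

    def resolve(self, dataset: PairDataset) -> tuple[PseKNCConfig, PseKNCConfig]:
        lmin = corpus_min_length(dataset.aptamers.values())
        lam2 = self.lambda_2 if self.lambda_2 is not None else lmin - 2
        lam3 = self.lambda_3 if self.lambda_3 is not None else lmin - 3
        return PseKNCConfig(2, lam2, self.omega), PseKNCConfig(3, lam3, self.omega)


def build_feature_matrix(
    dataset: PairDataset,
    pssms: Mapping[str, PSSMProfile],
    tracks: Mapping[str, DisorderTrack],
    config: EncoderConfig | None = None,
    tables: dict[int, KTuplePropertyTable] | None = None,
    scales: dict[str, HydropathyScale] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Encode every pair; returns (matrix, feature_dictionary).

    The matrix is a pairs x features DataFrame (index ``aptamer_id|protein_id``)
    whose last metadata is carried separately: ``dataset.labels`` aligns row-wise.
    A protein without a PSSM gets the zero-matrix fallback with a logged warning;
    a missing disorder track is a hard error.
    """
    if config is None:
        config = EncoderConfig()
    if tables is None:
        tables = {2: load_default_table(2), 3: load_default_table(3)}
    if scales is None:
        scales = load_default_scales()
    cfg2, cfg3 = config.resolve(dataset)

    apt_cache: dict[str, np.ndarray] = {}
    prot_cache: dict[str, np.ndarray] = {}
    apt_names: list[str] = []
    prot_names: list[str] = []

    for aid, seq in dataset.aptamers.items():
        apt_cache[aid], apt_names = encode_aptamer(seq, tables, {2: cfg2, 3: cfg3})
    for pid, prot in dataset.proteins.items():
        profile = pssms.get(pid)
        if profile is None:
            logger.warning("no PSSM for protein %s; substituting a zero matrix", pid)
            profile = PSSMProfile.zero(pid, len(prot))
        if pid not in tracks:
            raise ValidationError(f"no disorder track for protein {pid!r}")
        prot_cache[pid], prot_names = encode_protein(
            prot, profile, tracks[pid], scales, config.protein
        )

    names = apt_names + prot_names
    rows = np.empty((len(dataset.pairs), len(names)))
    index = []
    for i, pair in enumerate(dataset.pairs):
        rows[i] = np.concatenate([apt_cache[pair.aptamer_id], prot_cache[pair.protein_id]])
        index.append(f"{pair.aptamer_id}|{pair.protein_id}")
    matrix = pd.DataFrame(rows, index=index, columns=names)
    logger.info(
        "feature matrix: %d pairs x %d features (%d aptamer + %d protein)",
        matrix.shape[0], matrix.shape[1], len(apt_names), len(prot_names),
    )
    feature_dict = feature_dictionary(names)
    return matrix, feature_dict


def feature_dictionary(names: list[str]) -> pd.DataFrame:
    """Name / block / within-block index table exported alongside every matrix."""
    records = []
    counters: dict[str, int] = {}
    for name in names:
        if name.startswith("pse2"):
            block = "pseknc2"
        elif name.startswith("pse3"):
            block = "pseknc3"
        elif name.startswith("dct"):
            block = "dct"
        elif name.startswith("bg_"):
            block = "bigram_pssm"
        else:
            block = "disorder"
        idx = counters.get(block, 0)
        counters[block] = idx + 1
        records.append({"name": name, "block": block, "index": idx})
    return pd.DataFrame.from_records(records)
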