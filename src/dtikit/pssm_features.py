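"""PSSM-derived protein encoders: flattened profile and pseudo-PSSM.

The flattened profile ("PSSM" encoder, 20 x L_fixed = 2000 components)
uses a length-normalized matrix; the pseudo-PSSM summary ("PSEPSSM",
20 + 20 x eps_max = 220 components) is computed on the original-length
matrix, since its lag terms use the true sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dtikit.io_formats import STANDARD_AA, PSSMMatrix
from dtikit.protein_encoders import FeatureBlock


@dataclass(frozen=True)
class PsePSSMConfig:
    """Maximum correlation lag; must stay below the length of every PSSM."""

    epsilon_max: int = 10

    def __post_init__(self) -> None:
        if self.epsilon_max < 1:
            raise ValueError("epsilon_max must be >= 1")


def normalize_pssm_length(pssm: PSSMMatrix, fixed_length: int = 100) -> PSSMMatrix:
    """Truncate to the first ``fixed_length`` rows or append zero rows."""
    L = pssm.length
    if L >= fixed_length:
        scores = pssm.scores[:fixed_length]
        residues = pssm.row_residues[:fixed_length]
    else:
        pad = np.zeros((fixed_length - L, 20), dtype=pssm.scores.dtype)
        scores = np.vstack([pssm.scores, pad])
        residues = pssm.row_residues
    return PSSMMatrix(pssm.protein_id, scores, residues)


def flatten_pssm(pssm_norm: PSSMMatrix) -> FeatureBlock:
    """Row-major flattening of a length-normalized PSSM (position 1 first)."""
    L = pssm_norm.length
    names = tuple(
        f"PSSM_p{i + 1}_{a}" for i in range(L) for a in STANDARD_AA
    )
    return FeatureBlock("PSSM", pssm_norm.scores.ravel().astype(float), names)


def encode_psepssm(pssm: PSSMMatrix, config: PsePSSMConfig = PsePSSMConfig()) -> FeatureBlock:
    """Pseudo-PSSM: 20 column means plus 20 lagged squared-difference terms per lag.

    Component p_j is the mean score of column j; for each lag eps in
    1..eps_max, p_j^eps = (1/(L-eps)) * sum_i (P(i,j) - P(i+eps,j))^2.
    Raw scores are used without rescaling.
    """
    L = pssm.length
    if L <= config.epsilon_max:
        raise ValueError(
            f"PsePSSM needs L > epsilon_max={config.epsilon_max}, got L={L}"
        )
    scores = pssm.scores.astype(float)
    parts = [scores.mean(axis=0)]
    names = [f"PSEPSSM_mean_{a}" for a in STANDARD_AA]
    for eps in range(1, config.epsilon_max + 1):
        diffs = scores[:-eps] - scores[eps:]
        parts.append((diffs**2).sum(axis=0) / (L - eps))
        names.extend(f"PSEPSSM_lag{eps}_{a}" for a in STANDARD_AA)
    return FeatureBlock("PSEPSSM", np.concatenate(parts), tuple(names))


def pssm_encoder_dimensions(
    fixed_length: int = 100, config: PsePSSMConfig = PsePSSMConfig()
) -> dict[str, int]:
    return {
        "PSSM": 20 * fixed_length,
        "PSEPSSM": 20 * (1 + config.epsilon_max),
    }
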