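"""Assemble labeled drug-protein pair feature matrices.

A pair's feature vector is the protein descriptor vector of the chosen
combination mode followed by the drug's 881-bit fingerprint.  Listed
interactions are the positives; negatives are drawn uniformly without
replacement from the unlisted (drug, protein) pairs, which treats the
unknown pairs as non-interacting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from dtikit.io_formats import (
    FINGERPRINT_LENGTH,
    DrugRecord,
    InteractionList,
    ProteinRecord,
    PSSMMatrix,
)
from dtikit.protein_encoders import (
    SEQUENCE_ENCODERS,
    EncoderConfig,
    TfidfModel,
    encode,
    encoder_dimensions,
)
from dtikit.pssm_features import (
    PsePSSMConfig,
    encode_psepssm,
    flatten_pssm,
    normalize_pssm_length,
    pssm_encoder_dimensions,
)

#: Encoder line-ups of the three combination modes.  Protein-side widths
#: under the default config: MODE_A = 2125, MODE_B = 4625, MODE_C = 5414.
MODE_ENCODERS: dict[str, tuple[str, ...]] = {
    "MODE_A": ("PSSM", "EGAAC", "EAAC"),
    "MODE_B": ("PSSM", "EGAAC", "EAAC", "DDE", "BINA"),
    "MODE_C": (
        "PSSM", "EGAAC", "EAAC", "DDE", "BINA",
        "1GRAM", "2GRAM", "TFIDF", "NUM", "PSEPSSM", "PSEAAC",
    ),
}

PSSM_ENCODERS = ("PSSM", "PSEPSSM")


@dataclass(frozen=True)
class CombinationMode:
    """A named, ordered list of protein encoders to concatenate."""

    name: str
    encoder_list: tuple[str, ...]

    @classmethod
    def from_name(cls, name: str) -> "CombinationMode":
        key = name.upper()
        if not key.startswith("MODE_"):
            key = f"MODE_{key}"
        if key not in MODE_ENCODERS:
            raise ValueError(
                f"unknown combination mode {name!r}; choose from A, B, C"
            )
        return cls(key, MODE_ENCODERS[key])

    def protein_dimension(
        self,
        config: EncoderConfig = EncoderConfig(),
        psepssm_config: PsePSSMConfig = PsePSSMConfig(),
    ) -> int:
        dims = encoder_dimensions(config)
        dims.update(pssm_encoder_dimensions(config.fixed_length, psepssm_config))
        return sum(dims[e] for e in self.encoder_list)


@dataclass
class LabeledPairSet:
    """Labeled pair rows: ids, named feature matrix and binary labels."""

    pair_ids: list[tuple[str, str]]
    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        n = len(self.pair_ids)
        if self.X.shape[0] != n or self.y.shape[0] != n:
            raise ValueError("pair_ids, X rows and y must have equal counts")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if len(set(self.pair_ids)) != n:
            raise ValueError("duplicate pair ids")
        if self.feature_names and len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must match X columns")

    def __len__(self) -> int:
        return len(self.pair_ids)

    def subset(self, rows: Sequence[int]) -> "LabeledPairSet":
        rows = list(rows)
        return LabeledPairSet(
            [self.pair_ids[i] for i in rows],
            self.X[rows],
            self.y[rows],
            list(self.feature_names),
        )

    def select_columns(self, cols: Sequence[int]) -> "LabeledPairSet":
        cols = list(cols)
        return LabeledPairSet(
            list(self.pair_ids),
            self.X[:, cols],
            self.y,
            [self.feature_names[i] for i in cols] if self.feature_names else [],
        )


def protein_feature_vector(
    protein: ProteinRecord,
    pssm: PSSMMatrix | None,
    mode: CombinationMode,
    config: EncoderConfig = EncoderConfig(),
    psepssm_config: PsePSSMConfig = PsePSSMConfig(),
    tfidf_model: TfidfModel | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Concatenate the mode's encoder blocks in declared order.

    Returns the vector and its per-component feature names.  Modes that
    include a PSSM-derived encoder require the protein's PSSM.
    """
    values: list[np.ndarray] = []
    names: list[str] = []
    for enc in mode.encoder_list:
        if enc in PSSM_ENCODERS:
            if pssm is None:
                raise ValueError(
                    f"mode {mode.name} requires a PSSM for protein {protein.id!r}"
                )
            if enc == "PSSM":
                block = flatten_pssm(normalize_pssm_length(pssm, config.fixed_length))
            else:
                block = encode_psepssm(pssm, psepssm_config)
        elif enc in SEQUENCE_ENCODERS:
            block = encode(enc, protein, config, tfidf_model)
        else:
            raise KeyError(f"unknown encoder {enc!r} in mode {mode.name}")
        values.append(block.values)
        names.extend(block.feature_names)
    return np.concatenate(values), names


def build_pairs(
    proteins: Sequence[ProteinRecord],
    drugs: Sequence[DrugRecord],
    interactions: InteractionList,
    pssms: Mapping[str, PSSMMatrix] | None = None,
    mode: CombinationMode | str = "MODE_A",
    neg_ratio: float = 1.0,
    seed: int = 0,
    config: EncoderConfig = EncoderConfig(),
    psepssm_config: PsePSSMConfig = PsePSSMConfig(),
) -> LabeledPairSet:
    """Build the labeled pair set for a combination mode.

    Positives are the listed interactions (label 1); negatives are a
    seeded uniform sample without replacement of round(neg_ratio x
    positives) unlisted pairs.  Candidate negatives are enumerated in
    lexicographic (drug_id, protein_id) order and output rows are sorted
    by pair id before sampling, so the result is independent of input
    ordering.
    """
    if isinstance(mode, str):
        mode = CombinationMode.from_name(mode)
    protein_by_id = {p.id: p for p in proteins}
    drug_by_id = {d.id: d for d in drugs}
    pssms = pssms or {}

    for drug_id, protein_id in interactions:
        if drug_id not in drug_by_id:
            raise KeyError(f"interaction references unknown drug {drug_id!r}")
        if protein_id not in protein_by_id:
            raise KeyError(f"interaction references unknown protein {protein_id!r}")

    positives = sorted(interactions.pairs)
    positive_set = set(positives)
    candidates = [
        (d, p)
        for d in sorted(drug_by_id)
        for p in sorted(protein_by_id)
        if (d, p) not in positive_set
    ]
    n_neg = int(round(neg_ratio * len(positives)))
    if n_neg > len(candidates):
        raise ValueError(
            f"requested {n_neg} negatives but only {len(candidates)} unlisted pairs exist"
        )
    rng = np.random.default_rng(seed)
    neg_idx = rng.choice(len(candidates), size=n_neg, replace=False)
    negatives = sorted(candidates[i] for i in neg_idx)

    tfidf_model = None
    needs_tfidf = "TFIDF" in mode.encoder_list
    if needs_tfidf:
        from dtikit.protein_encoders import fit_tfidf

        tfidf_model = fit_tfidf(sorted(proteins, key=lambda p: p.id), config)

    # protein vectors are shared across pairs; encode each protein once
    protein_vectors: dict[str, np.ndarray] = {}
    protein_names: list[str] | None = None
    needed = {p for _, p in positives} | {p for _, p in negatives}
    for pid in sorted(needed):
        vec, names = protein_feature_vector(
            protein_by_id[pid], pssms.get(pid), mode, config, psepssm_config, tfidf_model
        )
        protein_vectors[pid] = vec
        protein_names = names

    assert protein_names is not None
    fp_names = [f"FP_{i + 1}" for i in range(FINGERPRINT_LENGTH)]
    pair_ids = positives + negatives
    labels = np.array([1] * len(positives) + [0] * len(negatives), dtype=int)
    X = np.empty((len(pair_ids), len(protein_names) + FINGERPRINT_LENGTH))
    for row, (drug_id, protein_id) in enumerate(pair_ids):
        X[row, : len(protein_names)] = protein_vectors[protein_id]
        X[row, len(protein_names) :] = drug_by_id[drug_id].fingerprint
    return LabeledPairSet(pair_ids, X, labels, protein_names + fp_names)
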