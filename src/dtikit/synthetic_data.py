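"""Seeded synthetic generators for every pipeline input.

Generates random protein sequences, PSSM profiles consistent with those
sequences, 881-bit drug fingerprints, and an interaction network with a
planted feature-to-label signal: a handful of assembled feature columns
drive a logistic model that labels each candidate drug-protein pair.
Planting the signal on assembled columns (rather than raw sequence
motifs) lets the selection and classification stages be tested
independently of encoder sensitivity.  All generators are pure
functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dtikit.io_formats import (
    FINGERPRINT_LENGTH,
    STANDARD_AA,
    DrugRecord,
    InteractionList,
    ProteinRecord,
    PSSMMatrix,
)
from dtikit.pair_assembly import CombinationMode, protein_feature_vector
from dtikit.protein_encoders import EncoderConfig, fit_tfidf
from dtikit.pssm_features import PsePSSMConfig


@dataclass(frozen=True)
class PlantedSignalSpec:
    """Study conditions for the synthetic benchmark.

    ``effect_size`` is the log-odds contribution per unit of each
    standardized planted feature column; ``intercept`` is the base
    log-odds, negative so that interactions are a minority of the
    candidate pairs (interaction networks are sparse, and sampled
    negatives must come from the unlisted pairs); ``noise_rate`` is the
    label flip probability after the logistic draw.
    """

    n_proteins: int = 40
    n_drugs: int = 30
    seq_length_range: tuple[int, int] = (60, 140)
    n_informative: int = 5
    effect_size: float = 2.0
    intercept: float = -2.0
    noise_rate: float = 0.05
    fingerprint_density: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative < 1:
            raise ValueError("n_informative must be >= 1")
        if not 0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must be in [0, 0.5)")
        lo, hi = self.seq_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid seq_length_range")


def gen_proteins(spec: PlantedSignalSpec) -> list[ProteinRecord]:
    """I.i.d. uniform sequences over the 20 standard residues, seeded."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.seq_length_range
    records = []
    for i in range(spec.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(STANDARD_AA[c] for c in rng.integers(0, 20, size=length))
        records.append(ProteinRecord(f"P{i + 1:04d}", seq))
    return records


def gen_pssm(protein: ProteinRecord, seed: int = 0) -> PSSMMatrix:
    """A synthetic PSSM: +5 at the observed residue, uniform -2..2 noise elsewhere.

    Stands in for a sequence profile so PSSM-based encoders run without
    an external profile search.
    """
    rng = np.random.default_rng(seed)
    L = len(protein.sequence)
    scores = rng.integers(-2, 3, size=(L, 20))
    index = {aa: i for i, aa in enumerate(STANDARD_AA)}
    for i, residue in enumerate(protein.sequence):
        if residue in index:
            scores[i, index[residue]] = 5
    return PSSMMatrix(protein.id, scores.astype(np.int64), protein.sequence)


def gen_pssms(proteins: list[ProteinRecord], seed: int = 0) -> dict[str, PSSMMatrix]:
    """One seeded PSSM per protein, derived deterministically from the base seed."""
    root = np.random.default_rng(seed)
    return {
        p.id: gen_pssm(p, seed=int(root.integers(2**31 - 1))) for p in proteins
    }


def gen_drugs(spec: PlantedSignalSpec) -> list[DrugRecord]:
    """881-bit fingerprints with independent per-bit activation probability."""
    rng = np.random.default_rng(spec.seed + 1)
    records = []
    for i in range(spec.n_drugs):
        bits = (rng.random(FINGERPRINT_LENGTH) < spec.fingerprint_density).astype(int)
        records.append(DrugRecord(f"D{i + 1:04d}", tuple(int(b) for b in bits)))
    return records


def _candidate_matrix(
    proteins: list[ProteinRecord],
    drugs: list[DrugRecord],
    pssms: dict[str, PSSMMatrix],
    mode: CombinationMode,
    config: EncoderConfig,
    psepssm_config: PsePSSMConfig,
) -> tuple[list[tuple[str, str]], np.ndarray, list[str]]:
    """Assembled feature matrix of every candidate (drug, protein) pair,
    enumerated in lexicographic order."""
    tfidf_model = (
        fit_tfidf(sorted(proteins, key=lambda p: p.id), config)
        if "TFIDF" in mode.encoder_list
        else None
    )
    protein_vecs: dict[str, np.ndarray] = {}
    names: list[str] | None = None
    for p in sorted(proteins, key=lambda p: p.id):
        vec, names = protein_feature_vector(
            p, pssms.get(p.id), mode, config, psepssm_config, tfidf_model
        )
        protein_vecs[p.id] = vec
    assert names is not None
    drug_by_id = {d.id: d for d in drugs}
    pair_ids = [
        (d, p) for d in sorted(drug_by_id) for p in sorted(protein_vecs)
    ]
    X = np.empty((len(pair_ids), len(names) + FINGERPRINT_LENGTH))
    for row, (d, p) in enumerate(pair_ids):
        X[row, : len(names)] = protein_vecs[p]
        X[row, len(names) :] = drug_by_id[d].fingerprint
    fp_names = [f"FP_{i + 1}" for i in range(FINGERPRINT_LENGTH)]
    return pair_ids, X, names + fp_names


def gen_interactions(
    proteins: list[ProteinRecord],
    drugs: list[DrugRecord],
    spec: PlantedSignalSpec,
    pssms: dict[str, PSSMMatrix] | None = None,
    mode: CombinationMode | str = "MODE_A",
    config: EncoderConfig = EncoderConfig(),
    psepssm_config: PsePSSMConfig = PsePSSMConfig(),
) -> tuple[InteractionList, list[str]]:
    """Plant a logistic feature-to-label signal and emit the interaction list.

    ``n_informative`` assembled feature columns are chosen at random
    (degenerate all-equal columns are re-drawn); each candidate pair is
    labeled by a Bernoulli draw from a logistic model with base log-odds
    ``intercept`` and coefficient ``effect_size`` on every standardized
    planted column, then flipped with probability ``noise_rate``.  Pairs labeled 1 become the
    interaction list; the planted column names are returned alongside.
    """
    if isinstance(mode, str):
        mode = CombinationMode.from_name(mode)
    if pssms is None:
        pssms = gen_pssms(proteins, seed=spec.seed + 2)
    pair_ids, X, feature_names = _candidate_matrix(
        proteins, drugs, pssms, mode, config, psepssm_config
    )
    rng = np.random.default_rng(spec.seed + 3)

    stds = X.std(axis=0)
    usable = np.flatnonzero(stds > 0)
    if usable.size < spec.n_informative:
        raise ValueError("not enough non-degenerate columns to plant the signal")
    planted = np.sort(rng.choice(usable, size=spec.n_informative, replace=False))

    Z = (X[:, planted] - X[:, planted].mean(axis=0)) / stds[planted]
    logits = spec.intercept + spec.effect_size * Z.sum(axis=1)
    p = 1.0 / (1.0 + np.exp(-logits))
    labels = rng.random(len(pair_ids)) < p
    flips = rng.random(len(pair_ids)) < spec.noise_rate
    labels = labels ^ flips

    interactions = InteractionList(
        [pair for pair, lab in zip(pair_ids, labels) if lab]
    )
    planted_names = [feature_names[j] for j in planted]
    return interactions, planted_names


@dataclass
class SyntheticDataset:
    """Everything one pipeline run needs, plus the planted ground truth."""

    spec: PlantedSignalSpec
    proteins: list[ProteinRecord]
    drugs: list[DrugRecord]
    pssms: dict[str, PSSMMatrix]
    interactions: InteractionList
    planted_features: list[str] = field(default_factory=list)


def gen_dataset(
    spec: PlantedSignalSpec,
    mode: CombinationMode | str = "MODE_A",
    config: EncoderConfig = EncoderConfig(),
    psepssm_config: PsePSSMConfig = PsePSSMConfig(),
) -> SyntheticDataset:
    """Generate proteins, PSSMs, drugs and a planted interaction network."""
    proteins = gen_proteins(spec)
    drugs = gen_drugs(spec)
    pssms = gen_pssms(proteins, seed=spec.seed + 2)
    interactions, planted = gen_interactions(
        proteins, drugs, spec, pssms, mode, config, psepssm_config
    )
    return SyntheticDataset(spec, proteins, drugs, pssms, interactions, planted)
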