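"""Protein sequence feature encoders producing fixed-length named vectors.

Ten sequence-derived descriptor families are implemented:

========  ====  ==========================================================
name       dim  description
========  ====  ==========================================================
EAAC       100  amino-acid composition in 5 equal sequence windows
EGAAC       25  5-group physicochemical composition in the same windows
DDE        400  dipeptide composition standardized against the codon-based
                theoretical mean/variance (deviation from expected mean)
TFIDF       20  per-residue term frequency x inverse document frequency
1GRAM       21  relative frequency of the 21 letters (incl. dummy 'O')
2GRAM      400  relative frequency of the 400 standard dipeptides
NUM        100  integer code (A=1 ... Y=20, O=21) per position
BINA      2100  position-wise one-hot over the 21-letter alphabet
PSEAAC      28  pseudo amino-acid composition (20 + lambda correlations)
========  ====  ==========================================================

Positional encoders (EAAC, EGAAC, NUM, BINA) operate on a sequence
normalized to a fixed length (truncate, or right-pad with the dummy
residue 'O'); composition encoders (DDE, TFIDF, k-gram, PSEAAC) operate
on the original sequence so padding cannot distort the composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from dtikit.io_formats import ALPHABET, DUMMY_AA, STANDARD_AA, ProteinRecord

# Sense-codon counts of the standard genetic code (stop codons excluded).
CODON_COUNTS = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2, "G": 4, "H": 2, "I": 3, "K": 2,
    "L": 6, "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6, "S": 6, "T": 4, "V": 4,
    "W": 1, "Y": 2,
}
TOTAL_CODONS = 61

# Physicochemical group definitions (aliphatic / aromatic / charged / uncharged).
EGAAC_GROUPS = {
    "aliphatic": "GAVLMI",
    "aromatic": "FYW",
    "positive": "KRH",
    "negative": "DE",
    "uncharged": "STCPNQ",
}

# Classic property scales used by pseudo amino-acid composition:
# hydrophobicity (Tanford), hydrophilicity (Hopp-Woods), side-chain mass.
HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
    "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
    "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
    "W": 0.81, "Y": 0.26,
}
HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
    "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
    "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
    "W": -3.4, "Y": -2.3,
}
SIDE_CHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
    "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0,
    "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0,
    "W": 130.0, "Y": 107.0,
}


@dataclass(frozen=True)
class EncoderConfig:
    """Tunable conventions shared by the encoders.

    ``fixed_length`` is the normalized sequence length; it must divide
    evenly into ``eaac_windows`` windows.  ``pseaac_lambda`` is the
    number of sequence-order correlation factors and must be smaller
    than the shortest sequence to encode; ``pseaac_weight`` balances
    composition against correlation terms.
    """

    fixed_length: int = 100
    eaac_windows: int = 5
    pseaac_lambda: int = 8
    pseaac_weight: float = 0.05
    tfidf_log_base: float = 10.0

    def __post_init__(self) -> None:
        if self.fixed_length <= 0 or self.eaac_windows <= 0:
            raise ValueError("fixed_length and eaac_windows must be positive")
        if self.fixed_length % self.eaac_windows != 0:
            raise ValueError("fixed_length must be divisible by eaac_windows")
        if self.pseaac_lambda <= 0:
            raise ValueError("pseaac_lambda must be positive")
        if self.pseaac_weight <= 0:
            raise ValueError("pseaac_weight must be positive")


@dataclass(frozen=True)
class FeatureBlock:
    """A named encoder output with per-component labels."""

    name: str
    values: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.feature_names),):
            raise ValueError(
                f"{self.name}: {self.values.shape[0]} values but "
                f"{len(self.feature_names)} feature names"
            )

    def __len__(self) -> int:
        return len(self.feature_names)


def normalize_sequence(seq: str, fixed_length: int = 100) -> str:
    """Truncate to the first ``fixed_length`` residues or right-pad with 'O'."""
    if not seq:
        raise ValueError("cannot normalize an empty sequence")
    if len(seq) >= fixed_length:
        return seq[:fixed_length]
    return seq + DUMMY_AA * (fixed_length - len(seq))


def _windows(seq_norm: str, config: EncoderConfig) -> list[str]:
    if len(seq_norm) != config.fixed_length:
        raise ValueError(
            f"expected normalized sequence of length {config.fixed_length}, "
            f"got {len(seq_norm)}"
        )
    w = config.fixed_length // config.eaac_windows
    return [seq_norm[i * w : (i + 1) * w] for i in range(config.eaac_windows)]


def encode_eaac(seq_norm: str, config: EncoderConfig = EncoderConfig()) -> FeatureBlock:
    """Windowed amino-acid composition: per-window residue frequencies.

    Each of the 5 equal windows contributes 20 components
    g(m, n) = H(m, n) / H(n), the count of residue m in window n over
    the window length.  Padding 'O' counts in the denominator only, so a
    fully padded window is all-zero.
    """
    values: list[float] = []
    names: list[str] = []
    for n, window in enumerate(_windows(seq_norm, config), start=1):
        denom = len(window)
        for m in STANDARD_AA:
            values.append(window.count(m) / denom)
            names.append(f"EAAC_w{n}_{m}")
    return FeatureBlock("EAAC", np.array(values), tuple(names))


def encode_egaac(seq_norm: str, config: EncoderConfig = EncoderConfig()) -> FeatureBlock:
    """Windowed grouped composition over 5 physicochemical residue groups."""
    values: list[float] = []
    names: list[str] = []
    for n, window in enumerate(_windows(seq_norm, config), start=1):
        denom = len(window)
        for group, members in EGAAC_GROUPS.items():
            count = sum(window.count(m) for m in members)
            values.append(count / denom)
            names.append(f"EGAAC_w{n}_{group}")
    return FeatureBlock("EGAAC", np.array(values), tuple(names))


def encode_dde(seq: str) -> FeatureBlock:
    """Dipeptide deviation from the expected mean (400 components).

    For each ordered standard dipeptide (m, n):

    - DC = H_mn / (H - 1), counted over adjacent pairs (pairs containing
      the dummy 'O' are skipped; H = number of standard residues);
    - TM = (C_m / 61) * (C_n / 61) from the sense-codon counts of the
      standard genetic code;
    - TV = TM * (1 - TM) / (H - 1);
    - DDE = (DC - TM) / sqrt(TV).
    """
    standard = [c for c in seq if c in STANDARD_AA]
    H = len(standard)
    if H < 2:
        raise ValueError("DDE needs at least two standard residues")
    counts = np.zeros((20, 20), dtype=float)
    index = {aa: i for i, aa in enumerate(STANDARD_AA)}
    for a, b in zip(seq, seq[1:]):
        if a in index and b in index:
            counts[index[a], index[b]] += 1
    dc = counts / (H - 1)
    codons = np.array([CODON_COUNTS[aa] for aa in STANDARD_AA], dtype=float)
    tm = np.outer(codons, codons) / (TOTAL_CODONS**2)
    tv = tm * (1.0 - tm) / (H - 1)
    dde = (dc - tm) / np.sqrt(tv)
    names = tuple(f"DDE_{m}{n}" for m in STANDARD_AA for n in STANDARD_AA)
    return FeatureBlock("DDE", dde.ravel(), names)


class TfidfModel:
    """Per-residue inverse document frequencies fitted on a protein corpus."""

    def __init__(self, idf: dict[str, float], n_documents: int):
        self.idf = dict(idf)
        self.n_documents = n_documents

    def __len__(self) -> int:
        return len(self.idf)


def fit_tfidf(
    corpus: Sequence[ProteinRecord], config: EncoderConfig = EncoderConfig()
) -> TfidfModel:
    """Fit per-residue IDF values: IDF(t) = log_base(|D| / DF(t)).

    DF(t) counts corpus sequences containing residue t; a residue absent
    from every document is smoothed with DF = 1.
    """
    if not corpus:
        raise ValueError("TF-IDF corpus must be non-empty")
    n_docs = len(corpus)
    log_base = np.log(config.tfidf_log_base)
    idf: dict[str, float] = {}
    for t in STANDARD_AA:
        df = sum(1 for rec in corpus if t in rec.sequence)
        idf[t] = float(np.log(n_docs / max(df, 1)) / log_base)
    return TfidfModel(idf, n_docs)


def encode_tfidf(seq: str, model: TfidfModel) -> FeatureBlock:
    """TF-IDF(t) = TF(t, d) * IDF(t) with TF = count of t / sequence length."""
    if not isinstance(model, TfidfModel):
        raise ValueError("encode_tfidf requires a fitted TfidfModel")
    length = len(seq)
    values = np.array(
        [seq.count(t) / length * model.idf[t] for t in STANDARD_AA], dtype=float
    )
    names = tuple(f"TFIDF_{t}" for t in STANDARD_AA)
    return FeatureBlock("TFIDF", values, names)


def encode_kgram(seq: str, k: int) -> FeatureBlock:
    """Relative k-gram frequencies.

    k=1: the 21 letters (dummy 'O' included), f(r) = N_r / N.
    k=2: the 400 standard dipeptides, f(r, s) = N_rs / (N - 1); pairs
    containing 'O' are skipped in the numerator.
    """
    if k == 1:
        if len(seq) < 1:
            raise ValueError("1-gram needs a non-empty sequence")
        n = len(seq)
        values = np.array([seq.count(r) / n for r in ALPHABET], dtype=float)
        names = tuple(f"1GRAM_{r}" for r in ALPHABET)
        return FeatureBlock("1GRAM", values, names)
    if k == 2:
        if len(seq) < 2:
            raise ValueError("2-gram needs a sequence of length >= 2")
        index = {aa: i for i, aa in enumerate(STANDARD_AA)}
        counts = np.zeros((20, 20), dtype=float)
        for a, b in zip(seq, seq[1:]):
            if a in index and b in index:
                counts[index[a], index[b]] += 1
        values = counts.ravel() / (len(seq) - 1)
        names = tuple(f"2GRAM_{r}{s}" for r in STANDARD_AA for s in STANDARD_AA)
        return FeatureBlock("2GRAM", values, names)
    raise ValueError(f"unsupported k-gram order: {k}")


#: Integer code per letter: A=1, C=2, ..., Y=20, dummy O=21.
NUM_CODES = {aa: i + 1 for i, aa in enumerate(ALPHABET)}


def encode_num(seq_norm: str, config: EncoderConfig = EncoderConfig()) -> FeatureBlock:
    """Integer alphabet code per position of the normalized sequence."""
    if len(seq_norm) != config.fixed_length:
        raise ValueError(f"expected normalized sequence of length {config.fixed_length}")
    values = np.array([NUM_CODES[c] for c in seq_norm], dtype=float)
    names = tuple(f"NUM_p{i + 1}" for i in range(config.fixed_length))
    return FeatureBlock("NUM", values, names)


def encode_bina(seq_norm: str, config: EncoderConfig = EncoderConfig()) -> FeatureBlock:
    """Position-wise one-hot encoding over the 21-letter alphabet."""
    if len(seq_norm) != config.fixed_length:
        raise ValueError(f"expected normalized sequence of length {config.fixed_length}")
    block = np.zeros((config.fixed_length, 21), dtype=float)
    for i, c in enumerate(seq_norm):
        block[i, NUM_CODES[c] - 1] = 1.0
    names = tuple(
        f"BINA_p{i + 1}_{a}" for i in range(config.fixed_length) for a in ALPHABET
    )
    return FeatureBlock("BINA", block.ravel(), names)


def _standardized_scales() -> np.ndarray:
    """The three PseAAC property scales standardized over the 20 residues.

    Standardization uses the population standard deviation over the 20
    amino acids, the usual convention for pseudo amino-acid composition.
    """
    scales = np.array(
        [
            [HYDROPHOBICITY[a] for a in STANDARD_AA],
            [HYDROPHILICITY[a] for a in STANDARD_AA],
            [SIDE_CHAIN_MASS[a] for a in STANDARD_AA],
        ],
        dtype=float,
    )
    mean = scales.mean(axis=1, keepdims=True)
    std = scales.std(axis=1, keepdims=True)
    return (scales - mean) / std


_PSEAAC_SCALES = _standardized_scales()


def encode_pseaac(seq: str, config: EncoderConfig = EncoderConfig()) -> FeatureBlock:
    """Pseudo amino-acid composition: 20 composition + lambda correlation terms.

    With f_u the residue frequencies and theta_k the order-k sequence
    correlation factor (mean squared property difference of residues k
    apart, averaged over the three standardized scales), the components
    are x_u = f_u / (sum f + w * sum theta) for u <= 20 and
    x_{20+k} = w * theta_k / (sum f + w * sum theta).  Dummy residues
    are removed before encoding.
    """
    lam = config.pseaac_lambda
    w = config.pseaac_weight
    standard = [c for c in seq if c in STANDARD_AA]
    if len(standard) <= lam:
        raise ValueError(
            f"PseAAC needs more than lambda={lam} standard residues, got {len(standard)}"
        )
    index = {aa: i for i, aa in enumerate(STANDARD_AA)}
    codes = np.array([index[c] for c in standard])
    L = len(codes)
    freqs = np.bincount(codes, minlength=20) / L

    props = _PSEAAC_SCALES[:, codes]  # 3 x L property values along the sequence
    thetas = np.empty(lam)
    for k in range(1, lam + 1):
        diffs = props[:, k:] - props[:, :-k]  # 3 x (L-k)
        thetas[k - 1] = np.mean(diffs**2, axis=0).sum() / (L - k)

    denom = freqs.sum() + w * thetas.sum()
    values = np.concatenate([freqs / denom, w * thetas / denom])
    names = tuple(f"PSEAAC_f_{a}" for a in STANDARD_AA) + tuple(
        f"PSEAAC_theta_{k}" for k in range(1, lam + 1)
    )
    return FeatureBlock("PSEAAC", values, names)


def encoder_dimensions(config: EncoderConfig = EncoderConfig()) -> dict[str, int]:
    """Declared output dimension per registered sequence encoder."""
    return {
        "EAAC": 20 * config.eaac_windows,
        "EGAAC": 5 * config.eaac_windows,
        "DDE": 400,
        "TFIDF": 20,
        "1GRAM": 21,
        "2GRAM": 400,
        "NUM": config.fixed_length,
        "BINA": 21 * config.fixed_length,
        "PSEAAC": 20 + config.pseaac_lambda,
    }


def encode(
    name: str,
    record: ProteinRecord,
    config: EncoderConfig = EncoderConfig(),
    tfidf_model: TfidfModel | None = None,
) -> FeatureBlock:
    """Run a registered sequence encoder by name on a protein record.

    Positional encoders receive the normalized sequence; composition
    encoders receive the original one.  TFIDF additionally requires a
    fitted :class:`TfidfModel`.
    """
    seq = record.sequence
    seq_norm = normalize_sequence(seq, config.fixed_length)
    dispatch: dict[str, Callable[[], FeatureBlock]] = {
        "EAAC": lambda: encode_eaac(seq_norm, config),
        "EGAAC": lambda: encode_egaac(seq_norm, config),
        "DDE": lambda: encode_dde(seq),
        "TFIDF": lambda: _require_tfidf(seq, tfidf_model),
        "1GRAM": lambda: encode_kgram(seq, 1),
        "2GRAM": lambda: encode_kgram(seq, 2),
        "NUM": lambda: encode_num(seq_norm, config),
        "BINA": lambda: encode_bina(seq_norm, config),
        "PSEAAC": lambda: encode_pseaac(seq, config),
    }
    if name not in dispatch:
        raise KeyError(f"unknown sequence encoder {name!r}")
    return dispatch[name]()


def _require_tfidf(seq: str, model: TfidfModel | None) -> FeatureBlock:
    if model is None:
        raise ValueError("TFIDF encoder requires a fitted TfidfModel")
    return encode_tfidf(seq, model)


SEQUENCE_ENCODERS = ("EAAC", "EGAAC", "DDE", "TFIDF", "1GRAM", "2GRAM", "NUM", "BINA", "PSEAAC")
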