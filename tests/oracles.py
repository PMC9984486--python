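"""Independent naive re-implementations of every encoder, used as oracles.

These are written with plain loops and their own copies of the constant
tables, deliberately sharing no code with the package beyond the raw
input values, so agreement is a meaningful check.
"""

import math

AA = "ACDEFGHIKLMNPQRSTVWY"
AA21 = AA + "O"

CODONS = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2, "G": 4, "H": 2, "I": 3, "K": 2,
    "L": 6, "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6, "S": 6, "T": 4, "V": 4,
    "W": 1, "Y": 2,
}

GROUPS = [("GAVLMI"), ("FYW"), ("KRH"), ("DE"), ("STCPNQ")]

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


def eaac(seq_norm, windows=5):
    w = len(seq_norm) // windows
    out = []
    for n in range(windows):
        chunk = seq_norm[n * w : (n + 1) * w]
        for m in AA:
            count = 0
            for ch in chunk:
                if ch == m:
                    count += 1
            out.append(count / len(chunk))
    return out


def egaac(seq_norm, windows=5):
    w = len(seq_norm) // windows
    out = []
    for n in range(windows):
        chunk = seq_norm[n * w : (n + 1) * w]
        for members in GROUPS:
            count = 0
            for ch in chunk:
                if ch in members:
                    count += 1
            out.append(count / len(chunk))
    return out


def dde(seq):
    standard = [c for c in seq if c in AA]
    H = len(standard)
    out = []
    for m in AA:
        for n in AA:
            h_mn = 0
            for i in range(len(seq) - 1):
                if seq[i] == m and seq[i + 1] == n:
                    h_mn += 1
            dc = h_mn / (H - 1)
            tm = (CODONS[m] / 61.0) * (CODONS[n] / 61.0)
            tv = tm * (1.0 - tm) / (H - 1)
            out.append((dc - tm) / math.sqrt(tv))
    return out


def tfidf(seq, corpus_seqs, base=10.0):
    n_docs = len(corpus_seqs)
    out = []
    for t in AA:
        df = 0
        for doc in corpus_seqs:
            if t in doc:
                df += 1
        idf = math.log(n_docs / max(df, 1), base)
        tf = seq.count(t) / len(seq)
        out.append(tf * idf)
    return out


def onegram(seq):
    return [seq.count(r) / len(seq) for r in AA21]


def twogram(seq):
    out = []
    for r in AA:
        for s in AA:
            count = 0
            for i in range(len(seq) - 1):
                if seq[i] == r and seq[i + 1] == s:
                    count += 1
            out.append(count / (len(seq) - 1))
    return out


def num(seq_norm):
    return [AA21.index(c) + 1 for c in seq_norm]


def bina(seq_norm):
    out = []
    for c in seq_norm:
        for a in AA21:
            out.append(1.0 if c == a else 0.0)
    return out


def _standardized(table):
    vals = [table[a] for a in AA]
    mean = sum(vals) / 20.0
    var = sum((v - mean) ** 2 for v in vals) / 20.0
    sd = math.sqrt(var)
    return {a: (table[a] - mean) / sd for a in AA}


def pseaac(seq, lam=8, w=0.05):
    scales = [
        _standardized(HYDROPHOBICITY),
        _standardized(HYDROPHILICITY),
        _standardized(SIDE_CHAIN_MASS),
    ]
    standard = [c for c in seq if c in AA]
    L = len(standard)
    freqs = [standard.count(a) / L for a in AA]
    thetas = []
    for k in range(1, lam + 1):
        total = 0.0
        for i in range(L - k):
            corr = 0.0
            for scale in scales:
                corr += (scale[standard[i]] - scale[standard[i + k]]) ** 2
            total += corr / 3.0
        thetas.append(total / (L - k))
    denom = sum(freqs) + w * sum(thetas)
    return [f / denom for f in freqs] + [w * t / denom for t in thetas]


def psepssm(matrix, eps_max=10):
    L = len(matrix)
    out = []
    for j in range(20):
        out.append(sum(matrix[i][j] for i in range(L)) / L)
    for eps in range(1, eps_max + 1):
        for j in range(20):
            total = 0.0
            for i in range(L - eps):
                total += (matrix[i][j] - matrix[i + eps][j]) ** 2
            out.append(total / (L - eps))
    return out
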