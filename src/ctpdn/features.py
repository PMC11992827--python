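"""Compound and protein descriptors for feature-based compound-target
interaction (CTI) modelling.

A compound is described by a molecular fingerprint (MACCS substructure keys,
167 positions, or ECFP6 — a circular fingerprint of radius 3 folded to 2048
bits) plus five precomputed ADMET property levels.  A protein is described by
29 sequence-derived physicochemical quantities: the 20 amino-acid composition
counts, theoretical pI, two molar extinction coefficients at 280 nm (all Cys
as cystine / all reduced), three N-end-rule half-life estimates (mammalian
reticulocyte, yeast, E. coli, in hours), the instability index, the aliphatic
index, and the grand average of hydropathicity (GRAVY).

Four dataset kinds combine the two fingerprints with the two sequence
variants of each target (full-length or motif): MF, MM, EF and EM.  MF/MM
tables carry 167 + 5 + 29 = 201 descriptor columns; EF/EM carry
2048 + 5 + 29 = 2082.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from Bio.SeqUtils import ProtParamData
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS = set("BZXU")

MACCS_BITS = 167  # position 0 is unused by the key definition but kept
ECFP6_BITS = 2048
ADMET_FIELDS = ("as", "bbb", "cyp2d6", "hepatotoxicity", "ppb")
N_PROTEIN_DESCRIPTORS = 29

_ecfp6_generator = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=ECFP6_BITS)

# extinction-coefficient constants at 280 nm (per Trp, per Tyr, per cystine)
_EPS_TRP, _EPS_TYR, _EPS_CYSTINE = 5500, 1490, 125

# N-end-rule half-lives by N-terminal residue, in hours:
# (mammalian reticulocytes in vitro, yeast in vivo, E. coli in vivo).
# Open-ended entries (">20 h", ">10 h") are encoded as their bound; the
# E. coli value for N-terminal Pro is not tabulated and is encoded as 10 h.
_MIN = 1.0 / 60.0
HALF_LIFE_HOURS: dict[str, tuple[float, float, float]] = {
    "A": (4.4, 20.0, 10.0),
    "R": (1.0, 2 * _MIN, 2 * _MIN),
    "N": (1.4, 3 * _MIN, 10.0),
    "D": (1.1, 3 * _MIN, 10.0),
    "C": (1.2, 20.0, 10.0),
    "E": (1.0, 30 * _MIN, 10.0),
    "Q": (0.8, 10 * _MIN, 10.0),
    "G": (30.0, 20.0, 10.0),
    "H": (3.5, 10 * _MIN, 10.0),
    "I": (20.0, 30 * _MIN, 10.0),
    "L": (5.5, 3 * _MIN, 2 * _MIN),
    "K": (1.3, 3 * _MIN, 2 * _MIN),
    "M": (30.0, 20.0, 10.0),
    "F": (1.1, 3 * _MIN, 2 * _MIN),
    "P": (20.0, 20.0, 10.0),
    "S": (1.9, 20.0, 10.0),
    "T": (7.2, 20.0, 10.0),
    "W": (2.8, 3 * _MIN, 2 * _MIN),
    "Y": (2.8, 10 * _MIN, 2 * _MIN),
    "V": (100.0, 20.0, 10.0),
}

# Side-chain and terminal pKa values (Bjellqvist set) for the net-charge
# model; the free termini take residue-specific pKa values where Bjellqvist
# tabulated them
_POSITIVE_PKS = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
_NEGATIVE_PKS = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
_NTERM_PKS = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}
_CTERM_PKS = {"D": 4.55, "E": 4.75}


# ---------------------------------------------------------------------------
# fingerprints


def _mol(smiles: str, compound_id: str | None = None):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        who = f" for compound {compound_id}" if compound_id else ""
        raise ValueError(f"unparseable SMILES{who}: {smiles!r}")
    return mol


def maccs_fp(smiles: str, compound_id: str | None = None) -> np.ndarray:
    """MACCS substructure keys as a 167-long 0/1 vector (position 0 unused)."""
    fp = MACCSkeys.GenMACCSKeys(_mol(smiles, compound_id))
    return np.array(fp, dtype=np.int8)


def ecfp6_fp(smiles: str, compound_id: str | None = None) -> np.ndarray:
    """ECFP6 circular fingerprint (radius 3) folded to 2048 bits."""
    fp = _ecfp6_generator.GetFingerprint(_mol(smiles, compound_id))
    return np.array(fp, dtype=np.int8)


# ---------------------------------------------------------------------------
# protein descriptors


def _clean_sequence(seq: str, tolerate_ambiguous: bool = False) -> str:
    """Validate a protein sequence; optionally strip ambiguous residues.

    With ``tolerate_ambiguous`` the letters B, Z, X and U are removed (they
    then contribute nothing to any descriptor); otherwise they are an error.
    """
    seq = seq.strip().upper()
    if not seq:
        raise ValueError("empty protein sequence")
    bad = set(seq) - set(AMINO_ACIDS)
    if bad - AMBIGUOUS:
        raise ValueError(f"invalid residue letter(s): {''.join(sorted(bad - AMBIGUOUS))}")
    if bad:
        if not tolerate_ambiguous:
            raise ValueError(
                f"ambiguous residue letter(s) {''.join(sorted(bad))}; "
                "pass tolerate_ambiguous=True to drop them"
            )
        seq = "".join(a for a in seq if a in AMINO_ACIDS)
        if not seq:
            raise ValueError("sequence empty after removing ambiguous residues")
    return seq


def aa_composition(seq: str, tolerate_ambiguous: bool = False) -> dict[str, int]:
    """Counts of the 20 standard amino acids; values sum to the (cleaned)
    sequence length."""
    seq = _clean_sequence(seq, tolerate_ambiguous)
    return {a: seq.count(a) for a in AMINO_ACIDS}


def gravy(seq: str, tolerate_ambiguous: bool = False) -> float:
    """Grand average of hydropathicity: mean Kyte-Doolittle hydropathy."""
    seq = _clean_sequence(seq, tolerate_ambiguous)
    return sum(ProtParamData.kd[a] for a in seq) / len(seq)


def aliphatic_index(seq: str, tolerate_ambiguous: bool = False) -> float:
    """Aliphatic index AI = X_Ala + 2.9 X_Val + 3.9 (X_Ile + X_Leu), with X
    the mole percent of each residue."""
    seq = _clean_sequence(seq, tolerate_ambiguous)
    n = len(seq)
    x = {a: 100.0 * seq.count(a) / n for a in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


def extinction_coefficients(seq: str, tolerate_ambiguous: bool = False) -> tuple[float, float]:
    """Molar extinction coefficients at 280 nm, ``(cystine, reduced)``.

    Reduced form: 5500 per Trp + 1490 per Tyr; the cystine form adds 125 per
    disulfide-paired cysteine couple (floor of nCys/2).
    """
    seq = _clean_sequence(seq, tolerate_ambiguous)
    reduced = _EPS_TRP * seq.count("W") + _EPS_TYR * seq.count("Y")
    cystine = reduced + _EPS_CYSTINE * (seq.count("C") // 2)
    return float(cystine), float(reduced)


def estimated_half_life(seq: str, tolerate_ambiguous: bool = False) -> tuple[float, float, float]:
    """N-end-rule half-life estimates (mammalian, yeast, E. coli) in hours,
    determined by the N-terminal residue alone."""
    seq = _clean_sequence(seq, tolerate_ambiguous)
    return HALF_LIFE_HOURS[seq[0]]


def instability_index(seq: str, tolerate_ambiguous: bool = False) -> float:
    """Instability index: (10/L) times the sum of dipeptide instability
    weights (Guruprasad table) over the L-1 overlapping dipeptides."""
    seq = _clean_sequence(seq, tolerate_ambiguous)
    if len(seq) < 2:
        raise ValueError("instability index needs at least one dipeptide (length >= 2)")
    total = sum(ProtParamData.DIWV[seq[i]][seq[i + 1]] for i in range(len(seq) - 1))
    return 10.0 * total / len(seq)


def _net_charge(seq: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge of a (clean) sequence at a given pH,
    with Bjellqvist's residue-specific free-terminus pKa values."""
    composition = {a: seq.count(a) for a in AMINO_ACIDS}
    nterm_pk = _NTERM_PKS.get(seq[0], _POSITIVE_PKS["Nterm"])
    cterm_pk = _CTERM_PKS.get(seq[-1], _NEGATIVE_PKS["Cterm"])
    pos = 1.0 / (1.0 + 10 ** (ph - nterm_pk))
    for a in "KRH":
        pos += composition[a] / (1.0 + 10 ** (ph - _POSITIVE_PKS[a]))
    neg = 1.0 / (1.0 + 10 ** (cterm_pk - ph))
    for a in "DECY":
        neg += composition[a] / (1.0 + 10 ** (_NEGATIVE_PKS[a] - ph))
    return pos - neg


def theoretical_pi(seq: str, tolerate_ambiguous: bool = False) -> float:
    """Theoretical isoelectric point: the pH of zero net charge, found by
    bisection on the Henderson-Hasselbalch charge function."""
    seq = _clean_sequence(seq, tolerate_ambiguous)
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if _net_charge(seq, mid) > 0:  # charge decreases monotonically in pH
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


PROTEIN_DESCRIPTOR_NAMES: list[str] = (
    [f"count_{a}" for a in AMINO_ACIDS]
    + ["pi", "ext_cystine", "ext_reduced",
       "half_life_mammal", "half_life_yeast", "half_life_ecoli",
       "instability", "aliphatic", "gravy"]
)


def protein_descriptor_vector(seq: str, tolerate_ambiguous: bool = False) -> np.ndarray:
    """The 29-entry physicochemical descriptor vector, in the fixed order of
    :data:`PROTEIN_DESCRIPTOR_NAMES`."""
    comp = aa_composition(seq, tolerate_ambiguous)
    eps_cystine, eps_reduced = extinction_coefficients(seq, tolerate_ambiguous)
    hl = estimated_half_life(seq, tolerate_ambiguous)
    vec = (
        [float(comp[a]) for a in AMINO_ACIDS]
        + [theoretical_pi(seq, tolerate_ambiguous), eps_cystine, eps_reduced,
           hl[0], hl[1], hl[2],
           instability_index(seq, tolerate_ambiguous),
           aliphatic_index(seq, tolerate_ambiguous),
           gravy(seq, tolerate_ambiguous)]
    )
    assert len(vec) == N_PROTEIN_DESCRIPTORS
    return np.array(vec, dtype=float)


# ---------------------------------------------------------------------------
# dataset assembly

DATASET_KINDS = ("MF", "MM", "EF", "EM")


def feature_columns(kind: str) -> list[str]:
    """Ordered descriptor-column roster for a dataset kind (no label)."""
    if kind not in DATASET_KINDS:
        raise ValueError(f"unknown dataset kind {kind!r}")
    if kind.startswith("M"):
        fp_cols = [f"maccs_{i}" for i in range(MACCS_BITS)]
    else:
        fp_cols = [f"ecfp6_{i}" for i in range(ECFP6_BITS)]
    admet_cols = [f"admet_{f}" for f in ADMET_FIELDS]
    prot_cols = [f"prot_{name}" for name in PROTEIN_DESCRIPTOR_NAMES]
    return fp_cols + admet_cols + prot_cols


def assemble_feature_table(
    pairs: pd.DataFrame,
    compounds: pd.DataFrame,
    sequences: dict[str, str],
    kind: str,
    tolerate_ambiguous: bool = False,
) -> pd.DataFrame:
    """Build a labelled feature table for compound-target pairs.

    ``pairs`` needs columns compound_id and target_id plus either an explicit
    ``label`` column or a docking ``success`` flag (success -> label 1).
    ``sequences`` maps ``"<target>|full"`` / ``"<target>|motif"`` FASTA ids to
    sequences; the dataset kind picks which variant is used (MF/EF full,
    MM/EM motif).  The result has the fixed descriptor roster of
    :func:`feature_columns` followed by a ``label`` column, and records its
    kind in ``df.attrs["kind"]``.
    """
    columns = feature_columns(kind)
    variant = "full" if kind.endswith("F") else "motif"
    fingerprint = maccs_fp if kind.startswith("M") else ecfp6_fp

    comp_idx = compounds.set_index("compound_id")
    if "label" in pairs.columns:
        labels = pairs["label"].astype(int)
    elif "success" in pairs.columns:
        labels = pairs["success"].astype(bool).astype(int)
    else:
        raise ValueError("pairs table needs a 'label' or 'success' column")

    fp_cache: dict[str, np.ndarray] = {}
    prot_cache: dict[str, np.ndarray] = {}
    rows = []
    for row, label in zip(pairs.itertuples(index=False), labels):
        cid, tid = str(row.compound_id), str(row.target_id)
        if cid not in comp_idx.index:
            raise ValueError(f"pair references unknown compound: {cid}")
        crec = comp_idx.loc[cid]
        if cid not in fp_cache:
            fp_cache[cid] = fingerprint(str(crec["smiles"]), cid).astype(float)
        key = f"{tid}|{variant}"
        if key not in sequences:
            raise ValueError(f"missing {variant!r} sequence for target {tid}")
        if key not in prot_cache:
            prot_cache[key] = protein_descriptor_vector(sequences[key], tolerate_ambiguous)
        admet = np.array([float(crec[f"admet_{f}"]) for f in ADMET_FIELDS])
        rows.append(np.concatenate([fp_cache[cid], admet, prot_cache[key], [label]]))

    df = pd.DataFrame(rows, columns=columns + ["label"])
    df["label"] = df["label"].astype(int)
    df.attrs["kind"] = kind
    return df


def drop_duplicate_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Remove descriptor columns whose values duplicate an earlier column
    across all rows (keeping the first occurrence); the label column always
    survives.  Idempotent."""
    if table.empty:
        return table.copy()
    features = table.drop(columns=["label"], errors="ignore")
    dup = features.T.duplicated()
    keep = [c for c in table.columns if c == "label" or not dup.get(c, False)]
    out = table[keep].copy()
    out.attrs = dict(table.attrs)
    return out
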