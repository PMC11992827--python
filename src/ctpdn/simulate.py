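"""Synthetic fixtures with known ground truth for every pipeline stage.

Three generators emulate a full study's input data at desk scale: database-style
network tables with one compound planted to bind uniformly stronger than the
rest, labelled compound-target pair datasets whose labels follow a known
fingerprint-bit/protein-property rule, and LC-MS-style peak tables with
planted differential features and pooled-QC replicate structure.  Every
generator is a pure function of (spec, seed) and emits a ground-truth record
alongside the data, so downstream recovery tests never re-derive the truth
from generator internals.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from . import io as wio
from .metabolomics import PeakTable, write_peak_table

#: amino-acid background frequencies (approximate database composition)
_AA_BACKGROUND = {
    "A": 0.083, "R": 0.055, "N": 0.041, "D": 0.055, "C": 0.014,
    "Q": 0.039, "E": 0.067, "G": 0.071, "H": 0.023, "I": 0.059,
    "L": 0.097, "K": 0.058, "M": 0.024, "F": 0.039, "P": 0.047,
    "S": 0.066, "T": 0.053, "W": 0.011, "Y": 0.029, "V": 0.069,
}

_SCAFFOLDS = ["c1ccccc1", "C1CCCCC1", "c1ccncc1", "C1CCOC1", "c1ccsc1", "c1ccoc1", ""]
_CHAINS = ["", "C", "CC", "CCC", "C(C)C", "CC(C)", "CCCC"]
_TERMINALS = ["", "O", "N", "Cl", "F", "C(=O)O", "OC", "C#N", "C(=O)N"]


@dataclass
class SimSpec:
    """Full parameterization of the synthetic study.

    Network block: layer sizes, edge densities and the docking-score model —
    reference scores s_m uniform over ``s_m_range``, candidate ratios
    s_i/s_m uniform over ``ratio_range``, and the planted compound's ratios
    multiplied by ``planted_multiplier`` (> 1 guarantees it out-binds every
    other compound on every target).

    CTI block: number of compounds/targets/pairs, the labelling rule
    (a MACCS fingerprint bit AND protein GRAVY above the target median,
    flipped with probability ``label_noise``), and sequence lengths.

    Metabolomics block: three groups (Con, Mod, BWG) of ``n_per_group``
    animals plus ``n_qc`` pooled-QC injections; planted features shift the
    Mod group mean by ``effect_size`` within-group standard deviations on the
    log10 scale, with BWG midway back toward Con.
    """

    seed: int = 0

    # network
    n_compounds: int = 10
    n_targets: int = 8
    n_pathways: int = 4
    n_diseases: int = 2
    cti_density: float = 0.6
    ppi_density: float = 0.3
    tpi_mean_members: int = 3
    s_m_range: tuple[float, float] = (20.0, 60.0)
    ratio_range: tuple[float, float] = (0.5, 1.0)
    planted_multiplier: float = 2.0

    # CTI dataset
    cti_n_compounds: int = 60
    cti_n_targets: int = 25
    n_pairs: int = 966
    fingerprint_bit: int | None = None  # None: pick a bit with usable prevalence
    label_noise: float = 0.0
    seq_length_range: tuple[int, int] = (50, 300)
    residue_background: str = "blosum"  # or "uniform"

    # metabolomics
    n_features: int = 200
    n_per_group: int = 6
    n_qc: int = 6
    n_planted: int = 3
    effect_size: float = 4.0
    log_sd: float = 0.2
    missing_rate: float = 0.05
    qc_rsd: float = 0.05
    noisy_qc_features: int = 0
    noisy_qc_rsd: float = 0.30

    def __post_init__(self) -> None:
        for name in ("n_compounds", "n_targets", "n_pathways", "n_diseases",
                     "cti_n_compounds", "cti_n_targets", "n_pairs",
                     "n_features", "n_per_group", "n_qc"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.label_noise < 1.0:
            raise ValueError("label_noise must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimSpec":
        d = dict(d)
        for key in ("s_m_range", "ratio_range", "seq_length_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# SMILES grammar


def enumerate_smiles() -> list[str]:
    """All parseable SMILES from the scaffold+chain+terminal grammar, in a
    fixed deterministic order."""
    from rdkit import Chem

    out: list[str] = []
    seen: set[str] = set()
    for scaffold in _SCAFFOLDS:
        for chain in _CHAINS:
            for terminal in _TERMINALS:
                smiles = scaffold + chain + terminal
                if not smiles:
                    continue
                mol = Chem.MolFromSmiles(smiles)
                if mol is None:
                    continue
                canonical = Chem.MolToSmiles(mol)
                if canonical not in seen:
                    seen.add(canonical)
                    out.append(smiles)
    return out


def _random_sequence(rng: np.random.Generator, length: int, background: str) -> str:
    letters = list(_AA_BACKGROUND)
    if background == "uniform":
        probs = np.full(20, 0.05)
    else:
        probs = np.array(list(_AA_BACKGROUND.values()))
        probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=length, p=probs))


# ---------------------------------------------------------------------------
# network fixture


def gen_network(spec: SimSpec) -> dict:
    """Generate docking, PPI, pathway and compound tables with one planted
    dominant compound.

    The planted compound docks successfully against every target with score
    ratios ``planted_multiplier`` times a draw from the shared ratio range,
    which (for multiplier x ratio strictly above the others' ratio maximum)
    makes every one of its compound-target edges strictly lighter than any
    competitor's, hence its shortest path to every disease strictly shortest.
    Returns a dict with the tables and a ``truth`` record naming the expected
    rank-1 compound and its expected shortest-path node sequence per disease
    (found by brute-force enumeration over layered paths).
    """
    rng = np.random.default_rng(spec.seed)
    compound_ids = [f"C{i:03d}" for i in range(spec.n_compounds)]
    target_ids = [f"T{i:03d}" for i in range(spec.n_targets)]
    pathway_ids = [f"P{i:03d}" for i in range(spec.n_pathways)]
    disease_ids = [f"D{i:03d}" for i in range(spec.n_diseases)]
    planted = compound_ids[int(rng.integers(spec.n_compounds))]

    lo, hi = spec.ratio_range
    if spec.planted_multiplier != 1.0:
        assert spec.planted_multiplier * lo >= hi, (
            "planted_multiplier too small to guarantee dominance over the ratio range"
        )

    docking_rows = []
    for c in compound_ids:
        for t in target_ids:
            success = c == planted or rng.random() < spec.cti_density
            s_m = float(rng.uniform(*spec.s_m_range))
            ratio = float(rng.uniform(lo, hi))
            if c == planted:
                ratio *= spec.planted_multiplier
            docking_rows.append({
                "compound_id": c, "target_id": t,
                "s_i": round(ratio * s_m, 4) if success else float("nan"),
                "s_m": round(s_m, 4), "success": success,
            })
    docking = pd.DataFrame(docking_rows)

    ppi_rows = []
    for i, a in enumerate(target_ids):
        for b in target_ids[i + 1:]:
            if rng.random() < spec.ppi_density:
                ppi_rows.append({
                    "target_a": a, "target_b": b,
                    "combined_score": round(float(rng.uniform(0.4, 0.999)), 3),
                })
    ppi = pd.DataFrame(ppi_rows, columns=["target_a", "target_b", "combined_score"])

    pathway_rows = []
    for p in pathway_ids:
        n_members = min(spec.n_targets, 1 + int(rng.poisson(spec.tpi_mean_members - 1)))
        members = sorted(rng.choice(target_ids, size=n_members, replace=False))
        n_dis = 1 + int(rng.integers(spec.n_diseases))
        diseases = sorted(rng.choice(disease_ids, size=n_dis, replace=False))
        pathway_rows.append({
            "pathway_id": p, "name": f"pathway {p}",
            "p_value": float(10 ** rng.uniform(-12, -9)),
            "q_value": float(10 ** rng.uniform(-10, -7)),
            "member_targets": wio.join_ids(members),
            "diseases": wio.join_ids(diseases),
        })
    pathways = pd.DataFrame(pathway_rows)

    smiles_pool = enumerate_smiles()
    picks = rng.choice(len(smiles_pool), size=spec.n_compounds, replace=False)
    compounds = pd.DataFrame({
        "compound_id": compound_ids,
        "smiles": [smiles_pool[i] for i in picks],
        "ob": np.round(rng.uniform(30, 90, spec.n_compounds), 2),
        "dl": np.round(rng.uniform(0.18, 0.9, spec.n_compounds), 3),
        "admet_as": rng.integers(0, 6, spec.n_compounds).astype(float),
        "admet_bbb": rng.integers(0, 5, spec.n_compounds).astype(float),
        "admet_cyp2d6": rng.integers(0, 2, spec.n_compounds).astype(float),
        "admet_hepatotoxicity": rng.integers(0, 2, spec.n_compounds).astype(float),
        "admet_ppb": rng.integers(0, 3, spec.n_compounds).astype(float),
    })

    truth = {
        "planted_compound": planted,
        "multiplier": spec.planted_multiplier,
        "expected_paths": _enumerate_best_paths(planted, docking, ppi, pathways),
    }
    return {"compounds": compounds, "docking": docking, "ppi": ppi,
            "pathways": pathways, "diseases": disease_ids, "truth": truth}


def _sigmoid_weight(S: float) -> float:
    return 1.0 / (1.0 + math.exp(-1.0 / S))


def _enumerate_best_paths(compound: str, docking, ppi, pathways) -> dict[str, dict]:
    """Brute-force the lightest layered path (up to 3 relayed targets) from
    one compound to each disease; independent of the shortest-path code."""
    cti = {
        (r.compound_id, r.target_id): _sigmoid_weight(r.s_i / r.s_m)
        for r in docking.itertuples() if r.success
    }
    tti: dict[tuple[str, str], float] = {}
    for r in ppi.itertuples():
        w = _sigmoid_weight(r.combined_score)
        tti[(r.target_a, r.target_b)] = tti[(r.target_b, r.target_a)] = w
    w_tpi = _sigmoid_weight(1.0)

    best: dict[str, tuple[float, list[str]]] = {}
    for p in pathways.itertuples():
        members = set(wio.split_ids(p.member_targets))
        for d in wio.split_ids(p.diseases):
            for (c, t1), w1 in cti.items():
                if c != compound:
                    continue
                chains: list[tuple[float, list[str]]] = []
                if t1 in members:
                    chains.append((w1, [t1]))
                for (a, t2), w2 in tti.items():
                    if a == t1 and t2 in members and t2 != t1:
                        chains.append((w1 + w2, [t1, t2]))
                    if a == t1 and t2 != t1:
                        for (a2, t3), w3 in tti.items():
                            if a2 == t2 and t3 in members and t3 not in (t1, t2):
                                chains.append((w1 + w2 + w3, [t1, t2, t3]))
                for w_chain, chain in chains:
                    length = w_chain + w_tpi + 1.0  # TPI weight + PDI weight
                    seq = [compound, *chain, p.pathway_id, d]
                    if d not in best or (length, seq) < best[d]:
                        best[d] = (length, seq)
    return {
        d: {"length": round(length, 12), "node_sequence": seq}
        for d, (length, seq) in sorted(best.items())
    }


# ---------------------------------------------------------------------------
# CTI dataset fixture


def gen_cti_dataset(spec: SimSpec) -> dict:
    """Generate compounds (grammar SMILES + fabricated ADMET levels), target
    sequences (full + motif), and labelled compound-target pairs.

    The label rule is: positive iff the compound's designated MACCS bit is
    set AND the target's full-length GRAVY exceeds the median target GRAVY,
    then flipped with probability ``label_noise``.  The bit is chosen (unless
    pinned in the spec) so the positive class lands in [0.3, 0.7].
    """
    rng = np.random.default_rng(spec.seed)
    smiles_pool = enumerate_smiles()
    if spec.cti_n_compounds > len(smiles_pool):
        raise ValueError(f"fragment grammar supplies only {len(smiles_pool)} compounds")
    picks = rng.choice(len(smiles_pool), size=spec.cti_n_compounds, replace=False)
    compound_ids = [f"C{i:03d}" for i in range(spec.cti_n_compounds)]
    compounds = pd.DataFrame({
        "compound_id": compound_ids,
        "smiles": [smiles_pool[i] for i in picks],
        "ob": np.round(rng.uniform(30, 90, spec.cti_n_compounds), 2),
        "dl": np.round(rng.uniform(0.18, 0.9, spec.cti_n_compounds), 3),
        "admet_as": rng.integers(0, 6, spec.cti_n_compounds).astype(float),
        "admet_bbb": rng.integers(0, 5, spec.cti_n_compounds).astype(float),
        "admet_cyp2d6": rng.integers(0, 2, spec.cti_n_compounds).astype(float),
        "admet_hepatotoxicity": rng.integers(0, 2, spec.cti_n_compounds).astype(float),
        "admet_ppb": rng.integers(0, 3, spec.cti_n_compounds).astype(float),
    })

    target_ids = [f"T{i:03d}" for i in range(spec.cti_n_targets)]
    sequences: dict[str, str] = {}
    for t in target_ids:
        length = int(rng.integers(spec.seq_length_range[0], spec.seq_length_range[1] + 1))
        seq = _random_sequence(rng, length, spec.residue_background)
        start = int(rng.integers(0, max(1, length - max(10, length // 4))))
        motif = seq[start:start + max(10, length // 4)]
        sequences[f"{t}|full"] = seq
        sequences[f"{t}|motif"] = motif

    maccs = {c: feat.maccs_fp(s) for c, s in zip(compound_ids, compounds["smiles"])}
    gravies = {t: feat.gravy(sequences[f"{t}|full"]) for t in target_ids}
    gravy_thr = float(np.median(list(gravies.values())))

    grid = [(c, t) for c in compound_ids for t in target_ids]
    if spec.n_pairs > len(grid):
        raise ValueError("n_pairs exceeds the compound x target grid")
    pair_idx = rng.choice(len(grid), size=spec.n_pairs, replace=False)
    pairs_ct = [grid[i] for i in pair_idx]

    def _labels_for_bit(bit: int) -> np.ndarray:
        return np.array(
            [int(maccs[c][bit] == 1 and gravies[t] > gravy_thr) for c, t in pairs_ct]
        )

    if spec.fingerprint_bit is not None:
        bit = spec.fingerprint_bit
        labels_clean = _labels_for_bit(bit)
    else:
        prevalence = np.array([np.mean([maccs[c][b] for c in compound_ids])
                               for b in range(feat.MACCS_BITS)])
        # GRAVY>median halves the positive rate, so aim the bit near 0.85
        for bit in np.argsort(np.abs(prevalence - 0.85), kind="stable"):
            labels_clean = _labels_for_bit(int(bit))
            if 0.3 <= labels_clean.mean() <= 0.7:
                bit = int(bit)
                break
        else:
            raise RuntimeError("no fingerprint bit yields a usable class balance")

    flips = rng.random(spec.n_pairs) < spec.label_noise
    labels = np.where(flips, 1 - labels_clean, labels_clean)
    pairs = pd.DataFrame({
        "compound_id": [c for c, _ in pairs_ct],
        "target_id": [t for _, t in pairs_ct],
        "label": labels,
    })
    truth = {
        "rule_bit": int(bit),
        "gravy_threshold": gravy_thr,
        "label_noise": spec.label_noise,
        "positive_rate": float(labels.mean()),
    }
    return {"compounds": compounds, "sequences": sequences, "pairs": pairs, "truth": truth}


# ---------------------------------------------------------------------------
# metabolomics fixture


def gen_peak_table(spec: SimSpec) -> dict:
    """Generate an LC-MS-style peak table for groups Con, Mod and BWG plus
    pooled-QC injections, with planted differential features.

    Feature intensities are lognormal: log10 baselines uniform in [4, 7],
    within-group log10 sd ``log_sd``.  Planted features shift the Mod mean
    up or down by ``effect_size`` x ``log_sd``; BWG sits midway between Con
    and Mod (partial recovery).  QC log-noise is set so the raw-scale QC RSD
    matches ``qc_rsd`` (``noisy_qc_features`` instead get ``noisy_qc_rsd``,
    which the QC filter should remove).  Values go missing completely at
    random at ``missing_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    feature_ids = [f"F{i:04d}" for i in range(spec.n_features)]
    groups = ["Con", "Mod", "BWG"]
    sample_names = [f"{g}{i + 1}" for g in groups for i in range(spec.n_per_group)]
    sample_names += [f"QC{i + 1}" for i in range(spec.n_qc)]
    group_labels = [g for g in groups for _ in range(spec.n_per_group)]
    group_labels += ["QC"] * spec.n_qc
    is_qc = [g == "QC" for g in group_labels]

    if spec.n_planted > spec.n_features:
        raise ValueError("n_planted exceeds n_features")
    planted = sorted(rng.choice(spec.n_features, size=spec.n_planted, replace=False).tolist())
    directions = rng.choice([-1.0, 1.0], size=spec.n_planted)
    noisy_qc = sorted(
        rng.choice(
            [i for i in range(spec.n_features) if i not in planted],
            size=min(spec.noisy_qc_features, spec.n_features - spec.n_planted),
            replace=False,
        ).tolist()
    ) if spec.noisy_qc_features else []

    baseline = rng.uniform(4.0, 7.0, spec.n_features)
    # planted biomarkers are quantifiable peaks, not near the detection
    # limit: draw their baselines from the upper half of the intensity range
    # so the variance filter (which acts on raw-scale SD) cannot discard them
    baseline[planted] = rng.uniform(5.5, 7.0, spec.n_planted)
    mod_shift = np.zeros(spec.n_features)
    for j, direction in zip(planted, directions):
        mod_shift[j] = direction * spec.effect_size * spec.log_sd

    def _qc_log_sd(rsd: float) -> float:
        return math.sqrt(math.log1p(rsd ** 2)) / math.log(10)

    qc_sd = np.full(spec.n_features, _qc_log_sd(spec.qc_rsd))
    for j in noisy_qc:
        qc_sd[j] = _qc_log_sd(spec.noisy_qc_rsd)

    log_values = np.empty((spec.n_features, len(sample_names)))
    for s, g in enumerate(group_labels):
        if g == "QC":
            mu = baseline + mod_shift / 2.0  # pooled mix of all groups
            log_values[:, s] = rng.normal(mu, qc_sd)
        else:
            shift = {"Con": 0.0, "Mod": 1.0, "BWG": 0.5}[g]
            mu = baseline + shift * mod_shift
            log_values[:, s] = rng.normal(mu, spec.log_sd)

    values = 10.0 ** log_values
    if spec.missing_rate > 0:
        # dropout hits only biological injections: the pooled QC mixes
        # contain every analyte of every group, so their peaks are present
        mask = rng.random(values.shape) < spec.missing_rate
        mask[:, np.array(is_qc)] = False
        values = np.where(mask, np.nan, values)

    intensities = pd.DataFrame(values, index=feature_ids, columns=sample_names)
    mz = pd.Series(np.round(rng.uniform(70, 1200, spec.n_features), 4), index=feature_ids)
    table = PeakTable(
        intensities=intensities,
        groups=pd.Series(group_labels, index=sample_names),
        is_qc=pd.Series(is_qc, index=sample_names),
        mz=mz,
        log=[f"simulated: {spec.n_features} features"],
    )
    truth = {
        "planted_features": [feature_ids[j] for j in planted],
        "directions": {feature_ids[j]: float(d) for j, d in zip(planted, directions)},
        "noisy_qc_features": [feature_ids[j] for j in noisy_qc],
        "effect_size": spec.effect_size,
    }
    return {"peaks": table, "truth": truth}


# ---------------------------------------------------------------------------
# fixture directory


def write_fixture_dir(spec: SimSpec, outdir: str | Path) -> Path:
    """Write every fixture family plus ``truth.json`` and the spec itself."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    net = gen_network(spec)
    wio.write_table(net["compounds"], outdir / "compounds.tsv", "compounds")
    wio.write_table(net["docking"], outdir / "docking.tsv", "docking")
    wio.write_table(net["ppi"], outdir / "ppi.tsv", "ppi")
    wio.write_table(net["pathways"], outdir / "pathways.tsv", "pathways")

    cti = gen_cti_dataset(spec)
    wio.write_table(cti["compounds"], outdir / "cti_compounds.tsv", "compounds")
    wio.write_fasta(cti["sequences"], outdir / "sequences.fasta")
    cti["pairs"].to_csv(outdir / "cti_pairs.tsv", sep="\t", index=False)

    met = gen_peak_table(spec)
    write_peak_table(met["peaks"], outdir / "peaks.tsv")

    truth = {"network": net["truth"], "cti": cti["truth"], "metabolomics": met["truth"]}
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    (outdir / "simspec.json").write_text(json.dumps(spec.to_dict(), indent=2) + "\n")
    return outdir
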