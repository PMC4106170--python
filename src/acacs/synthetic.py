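"""Synthetic fixtures: shift corpora with known cell means, labeled datasets.

Two generators:

- :func:`generate_shift_corpus` emulates a curated corpus of assigned
  backbone shifts.  Every residue of every protein emits one observation
  per applicable atom (proline emits no amide proton), drawn from
  Normal(true_mean(cell), sigma).  The true means are known to the caller,
  so table builds can be checked by parameter recovery, and a complete
  emission log audits every draw.

- :func:`generate_labeled_dataset` emulates a labeled classification
  dataset.  Each class has its own residue distribution and SS-state
  distribution; the "SS-only signal" preset gives all classes the same
  residue distribution but different SS compositions, so composition
  features (AAC/DC) carry no class signal while chemical-shift features do
  — the construction behind the ablation experiments.

Default cell means are approximate literature random-coil shifts for the
four backbone nuclei plus conventional secondary-structure offsets (helix
moves 13Ca downfield and 1Ha upfield, strands the reverse); they reproduce
the qualitative dependence of averaged shifts on residue type and secondary
structure, not any specific published table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabets import AA_ORDER, ATOM_ORDER, PROLINE, SS_ORDER
from .model_eval import LabeledDataset
from .star_io import ProteinSample, ShiftObservation, write_shift_file

# Approximate random-coil chemical shifts (ppm) per residue, per atom.
_COIL_H1A = {
    "A": 4.32, "C": 4.55, "D": 4.64, "E": 4.35, "F": 4.62, "G": 3.96,
    "H": 4.73, "I": 4.17, "K": 4.32, "L": 4.34, "M": 4.48, "N": 4.74,
    "P": 4.42, "Q": 4.34, "R": 4.34, "S": 4.47, "T": 4.35, "V": 4.12,
    "W": 4.66, "Y": 4.55,
}
_COIL_H1N = {
    "A": 8.24, "C": 8.32, "D": 8.34, "E": 8.42, "F": 8.30, "G": 8.33,
    "H": 8.42, "I": 8.00, "K": 8.29, "L": 8.16, "M": 8.28, "N": 8.40,
    "P": float("nan"), "Q": 8.32, "R": 8.23, "S": 8.31, "T": 8.15,
    "V": 8.03, "W": 8.25, "Y": 8.12,
}
_COIL_C13A = {
    "A": 52.5, "C": 58.2, "D": 54.2, "E": 56.6, "F": 57.7, "G": 45.1,
    "H": 55.0, "I": 61.1, "K": 56.2, "L": 55.1, "M": 55.4, "N": 53.1,
    "P": 63.3, "Q": 55.7, "R": 56.0, "S": 58.3, "T": 61.8, "V": 62.2,
    "W": 57.5, "Y": 57.9,
}
_COIL_N15 = {
    "A": 123.8, "C": 118.8, "D": 120.4, "E": 120.2, "F": 120.3, "G": 108.8,
    "H": 118.2, "I": 119.9, "K": 120.4, "L": 121.8, "M": 119.6, "N": 118.7,
    "P": 135.0, "Q": 119.8, "R": 120.5, "S": 115.7, "T": 113.6, "V": 119.2,
    "W": 121.3, "Y": 120.3,
}
_COIL = {"N15": _COIL_N15, "C13A": _COIL_C13A, "H1A": _COIL_H1A, "H1N": _COIL_H1N}

# Secondary-structure offsets (ppm) added to the coil value: (helix, strand).
_SS_OFFSET = {
    "N15": {"H": -1.5, "E": 2.0, "C": 0.0},
    "C13A": {"H": 2.6, "E": -1.4, "C": 0.0},
    "H1A": {"H": -0.35, "E": 0.40, "C": 0.0},
    "H1N": {"H": -0.10, "E": 0.20, "C": 0.0},
}


def default_true_means() -> dict[tuple[str, str, str], float]:
    """The generator's ground-truth cell means; proline H1N cells are absent."""
    means: dict[tuple[str, str, str], float] = {}
    for atom in ATOM_ORDER:
        for residue in AA_ORDER:
            if atom == "H1N" and residue == PROLINE:
                continue
            for ss in SS_ORDER:
                means[(atom, residue, ss)] = _COIL[atom][residue] + _SS_OFFSET[atom][ss]
    return means


@dataclass(frozen=True)
class SyntheticShiftConfig:
    """Corpus generator settings; proline H1N is never emitted."""

    n_proteins: int = 20
    length_range: tuple[int, int] = (60, 120)
    sigma_ppm: float = 0.3
    seed: int = 0
    true_means: dict[tuple[str, str, str], float] = field(
        default_factory=default_true_means
    )
    residue_probs: np.ndarray | None = None  # over AA_ORDER; uniform if None
    ss_probs: np.ndarray | None = None  # over (H, E, C); uniform if None
    ss_markov: bool = False  # draw SS as a sticky Markov chain (realistic runs)
    ss_stay_prob: float = 0.9

    def __post_init__(self):
        if self.sigma_ppm <= 0:
            raise ValueError("sigma_ppm must be positive")
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ValueError(f"bad length_range {self.length_range}")
        for (atom, residue, ss) in self.true_means:
            if atom == "H1N" and residue == PROLINE:
                raise ValueError("true_means must not contain proline H1N cells")


@dataclass
class ShiftCorpus:
    """Generated corpus: samples, per-draw emission log, and star-text export."""

    samples: list[ProteinSample]
    log: pd.DataFrame  # protein_id, residue_index, residue, ss, atom, shift_ppm

    def observations(self) -> list[ShiftObservation]:
        return [
            ShiftObservation(r.protein_id, int(r.residue_index), r.residue,
                             r.atom, float(r.shift_ppm))
            for r in self.log.itertuples(index=False)
        ]

    def star_text(self) -> str:
        return write_shift_file(self.observations())

    def log_tsv(self) -> str:
        return self.log.to_csv(sep="\t", index=False)


def _draw_ss(rng: np.random.Generator, L: int, probs: np.ndarray,
             markov: bool, stay: float) -> str:
    states = np.array(list(SS_ORDER))
    if not markov:
        return "".join(rng.choice(states, size=L, p=probs))
    # sticky chain: remain in the current state with prob `stay`, otherwise
    # re-draw from the stationary-ish base distribution
    out = [rng.choice(states, p=probs)]
    for _ in range(1, L):
        if rng.random() < stay:
            out.append(out[-1])
        else:
            out.append(rng.choice(states, p=probs))
    return "".join(out)


def generate_shift_corpus(config: SyntheticShiftConfig) -> ShiftCorpus:
    """Draw a deterministic star-style corpus from known cell distributions."""
    rng = np.random.default_rng(config.seed)
    aa = np.array(list(AA_ORDER))
    res_p = (np.full(20, 1 / 20) if config.residue_probs is None
             else np.asarray(config.residue_probs, dtype=float))
    ss_p = (np.full(3, 1 / 3) if config.ss_probs is None
            else np.asarray(config.ss_probs, dtype=float))

    samples: list[ProteinSample] = []
    cols: dict[str, list] = {k: [] for k in
                             ("protein_id", "residue_index", "residue", "ss",
                              "atom", "shift_ppm")}
    lo, hi = config.length_range
    for p in range(config.n_proteins):
        pid = f"SYN{p + 1:04d}"
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(aa, size=L, p=res_p))
        ss = _draw_ss(rng, L, ss_p, config.ss_markov, config.ss_stay_prob)
        samples.append(ProteinSample(pid, seq, ss))
        for pos, (j, k) in enumerate(zip(seq, ss), start=1):
            for atom in ATOM_ORDER:
                if atom == "H1N" and j == PROLINE:
                    continue
                mu = config.true_means.get((atom, j, k))
                if mu is None:
                    continue
                value = float(rng.normal(mu, config.sigma_ppm))
                cols["protein_id"].append(pid)
                cols["residue_index"].append(pos)
                cols["residue"].append(j)
                cols["ss"].append(k)
                cols["atom"].append(atom)
                cols["shift_ppm"].append(value)
    log = pd.DataFrame(cols)
    return ShiftCorpus(samples=samples, log=log)


@dataclass(frozen=True)
class ClassConfig:
    """One class's generative settings."""

    name: str
    ss_probs: tuple[float, float, float]  # over (H, E, C)
    residue_probs: tuple[float, ...] | None = None  # over AA_ORDER; uniform if None

    def __post_init__(self):
        if abs(sum(self.ss_probs) - 1.0) > 1e-9:
            raise ValueError(f"class {self.name}: ss_probs must sum to 1")
        if self.residue_probs is not None and abs(sum(self.residue_probs) - 1.0) > 1e-9:
            raise ValueError(f"class {self.name}: residue_probs must sum to 1")


@dataclass(frozen=True)
class SyntheticDatasetConfig:
    """Labeled-dataset generator settings."""

    classes: tuple[ClassConfig, ...]
    n_per_class: int = 50
    length_range: tuple[int, int] = (60, 120)
    seed: int = 0
    ss_markov: bool = False
    ss_stay_prob: float = 0.9

    def __post_init__(self):
        if len(self.classes) < 2:
            raise ValueError("need at least two classes")
        if self.n_per_class < 2:
            raise ValueError("need at least two samples per class")


def ss_only_signal_config(
    n_per_class: int = 50,
    h_gap: float = 0.2,
    length_range: tuple[int, int] = (60, 120),
    seed: int = 0,
) -> SyntheticDatasetConfig:
    """Two classes, identical (uniform) residue distributions, SS H-fraction
    differing by ``h_gap``: composition features carry no class signal,
    chemical-shift features do."""
    base_h = 0.35
    a = ClassConfig("helix_rich", (base_h + h_gap / 2, 0.25, 0.40 - h_gap / 2))
    b = ClassConfig("helix_poor", (base_h - h_gap / 2, 0.25, 0.40 + h_gap / 2))
    return SyntheticDatasetConfig(classes=(a, b), n_per_class=n_per_class,
                                  length_range=length_range, seed=seed)


def no_signal_config(
    n_per_class: int = 50,
    length_range: tuple[int, int] = (60, 120),
    seed: int = 0,
) -> SyntheticDatasetConfig:
    """Two classes with identical generative settings: chance-level target."""
    probs = (0.35, 0.25, 0.40)
    return SyntheticDatasetConfig(
        classes=(ClassConfig("null_a", probs), ClassConfig("null_b", probs)),
        n_per_class=n_per_class, length_range=length_range, seed=seed,
    )


def generate_labeled_dataset(config: SyntheticDatasetConfig) -> LabeledDataset:
    """Draw a deterministic labeled (sequence, SS) dataset per class config."""
    rng = np.random.default_rng(config.seed)
    aa = np.array(list(AA_ORDER))
    samples: list[ProteinSample] = []
    labels: list[str] = []
    lo, hi = config.length_range
    for cls in config.classes:
        res_p = (np.full(20, 1 / 20) if cls.residue_probs is None
                 else np.asarray(cls.residue_probs, dtype=float))
        ss_p = np.asarray(cls.ss_probs, dtype=float)
        for m in range(config.n_per_class):
            pid = f"{cls.name}_{m + 1:03d}"
            L = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(aa, size=L, p=res_p))
            ss = _draw_ss(rng, L, ss_p, config.ss_markov, config.ss_stay_prob)
            samples.append(ProteinSample(pid, seq, ss))
            labels.append(cls.name)
    return LabeledDataset(samples=tuple(samples), labels=tuple(labels))
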