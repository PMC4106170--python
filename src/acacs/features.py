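"""The acACS encoder and the classical composition features.

Given a protein P = [j_1 ... j_L] with aligned 3-state secondary structure
[k_1 ... k_L], each residue is replaced by the averaged chemical shift of
its (atom, residue type, SS state) cell, giving a per-atom numeric series
S_1 ... S_L.  The series is then summarised by its lagged mean-squared
differences

    theta(lam) = (1/(L - lam)) * sum_{l=1}^{L-lam} (S_l - S_{l+lam})^2

for lags 1..lam_max (a variogram-style statistic, called autocovariance in
this literature), with the lag-0 slot carrying the series mean.  One block
of lam_max + 1 numbers per selected atom, concatenated in the fixed atom
order N15, C13A, H1A, H1N, forms the acACS feature vector.  The amino-acid
composition (20 fractions) and dipeptide composition (400 ordered-pair
fractions) blocks can be fused onto it for classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acs_table import AcsTable
from .alphabets import AA_ORDER, ATOM_ORDER, check_atom
from .star_io import ProteinSample

MISSING_POLICIES = ("error", "cell_row_mean", "zero")

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
_DIPEPTIDES = [a + b for a in AA_ORDER for b in AA_ORDER]


class MissingCellError(KeyError):
    """Lookup hit a table cell with no observations under policy='error'."""


@dataclass(frozen=True)
class ShiftSeries:
    """The per-position ACS series S_1 ... S_L for one atom."""

    atom: str
    values: np.ndarray
    missing_positions: frozenset[int] = frozenset()  # 1-based

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FeatureVector:
    """An ordered feature vector with a named-component layout."""

    components: np.ndarray
    names: tuple[str, ...]
    lam: int | None = None

    def __post_init__(self):
        if len(self.components) != len(self.names):
            raise ValueError("component/name length mismatch")

    def __len__(self) -> int:
        return len(self.components)

    def block_kinds(self) -> set[str]:
        return {n.split("_", 1)[0] for n in self.names}


def lookup_series(
    sample: ProteinSample,
    table: AcsTable,
    atom: str,
    missing_policy: str = "cell_row_mean",
) -> ShiftSeries:
    """Replace every residue by its ACS value for ``atom`` (table lookup).

    ``missing_policy`` controls what happens at positions whose (atom,
    residue, SS) cell has no observations (proline amide protons being the
    structural case):

    - ``error``: raise, naming protein, position and cell;
    - ``cell_row_mean``: substitute the count-weighted mean of the same
      (atom, residue) across the SS states with data, falling back to the
      atom-wide mean;
    - ``zero``: substitute 0.0.

    The affected positions are recorded in ``missing_positions`` regardless.
    """
    check_atom(atom)
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    grid = table.lookup_grid(atom)  # residues x (H, E, C) means
    counts = (
        table.frame.xs(atom, level="atom")["count"]
        .unstack("ss")
        .reindex(index=grid.index, columns=grid.columns)
        .fillna(0)
    )
    values = np.empty(sample.L)
    missing: list[int] = []
    for pos, (j, k) in enumerate(zip(sample.sequence, sample.ss), start=1):
        mean = grid.at[j, k]
        if np.isnan(mean):
            missing.append(pos)
            if missing_policy == "error":
                raise MissingCellError(
                    f"{sample.protein_id} position {pos}: ACS cell "
                    f"({atom}, {j}, {k}) has no observations"
                )
            if missing_policy == "zero":
                mean = 0.0
            else:  # cell_row_mean
                row_means = grid.loc[j].to_numpy(dtype=float)
                row_counts = counts.loc[j].to_numpy(dtype=float)
                ok = ~np.isnan(row_means) & (row_counts > 0)
                if ok.any():
                    mean = float(np.average(row_means[ok], weights=row_counts[ok]))
                else:
                    atom_frame = table.frame.xs(atom, level="atom")
                    w = atom_frame["count"].to_numpy(dtype=float)
                    m = atom_frame["mean_ppm"].to_numpy(dtype=float)
                    ok = ~np.isnan(m) & (w > 0)
                    mean = float(np.average(m[ok], weights=w[ok]))
        values[pos - 1] = mean
    return ShiftSeries(atom, values, frozenset(missing))


def autocovariance(series, lam: int) -> float:
    """theta(lam): mean squared difference between S_l and S_{l+lam}.

    Requires 0 < lam < L.  Always non-negative; zero exactly when the
    series is lam-periodic in the matched positions.
    """
    values = np.asarray(series.values if isinstance(series, ShiftSeries) else series,
                        dtype=float)
    L = len(values)
    if not 0 < lam < L:
        raise ValueError(f"lag must satisfy 0 < lam < L; got lam={lam}, L={L}")
    diffs = values[:-lam] - values[lam:]
    return float(np.mean(diffs * diffs))


def series_mean(series) -> float:
    """The series mean, carried in the lag-0 slot of the acACS block."""
    values = np.asarray(series.values if isinstance(series, ShiftSeries) else series,
                        dtype=float)
    if len(values) == 0:
        raise ValueError("empty series has no mean")
    return float(np.mean(values))


def encode_acacs(
    sample: ProteinSample,
    table: AcsTable,
    atoms: tuple[str, ...] = ATOM_ORDER,
    lam_max: int = 12,
    missing_policy: str = "cell_row_mean",
) -> FeatureVector:
    """Encode a (sequence, SS) pair as the acACS vector.

    Per selected atom, in the fixed atom order, the block is
    [mean(S), theta(1), ..., theta(lam_max)] — lam_max + 1 components —
    so the full vector has |atoms| * (lam_max + 1) components.
    ``lam_max`` must be smaller than the sequence length.
    """
    if not atoms:
        raise ValueError("at least one atom must be selected")
    ordered = [a for a in ATOM_ORDER if a in set(atoms)]
    for a in atoms:
        check_atom(a)
    if not 0 < lam_max < sample.L:
        raise ValueError(
            f"{sample.protein_id}: lam_max={lam_max} must satisfy "
            f"0 < lam_max < L (L={sample.L})"
        )
    components: list[float] = []
    names: list[str] = []
    for atom in ordered:
        series = lookup_series(sample, table, atom, missing_policy)
        components.append(series_mean(series))
        names.append(f"acACS_{atom}_mean")
        for lam in range(1, lam_max + 1):
            components.append(autocovariance(series, lam))
            names.append(f"acACS_{atom}_lag{lam}")
    return FeatureVector(np.array(components), tuple(names), lam=lam_max)


def aac(sequence: str) -> FeatureVector:
    """Amino-acid composition: 20 residue fractions, alphabetical order."""
    if not sequence:
        raise ValueError("empty sequence")
    counts = np.zeros(20)
    for pos, ch in enumerate(sequence, start=1):
        idx = _AA_INDEX.get(ch)
        if idx is None:
            raise ValueError(f"non-standard residue {ch!r} at position {pos}")
        counts[idx] += 1
    return FeatureVector(counts / len(sequence),
                         tuple(f"AAC_{a}" for a in AA_ORDER))


def dc(sequence: str) -> FeatureVector:
    """Dipeptide composition: 400 ordered-pair fractions over adjacent pairs."""
    if len(sequence) < 2:
        raise ValueError("dipeptide composition requires length >= 2")
    counts = np.zeros(400)
    for pos in range(len(sequence) - 1):
        a, b = sequence[pos], sequence[pos + 1]
        ia, ib = _AA_INDEX.get(a), _AA_INDEX.get(b)
        if ia is None or ib is None:
            bad = a if ia is None else b
            raise ValueError(f"non-standard residue {bad!r} near position {pos + 1}")
        counts[ia * 20 + ib] += 1
    return FeatureVector(counts / (len(sequence) - 1),
                         tuple(f"DC_{d}" for d in _DIPEPTIDES))


def fuse(blocks: list[FeatureVector]) -> FeatureVector:
    """Concatenate feature blocks in the declared order.

    Blocks must come from the same sample; a duplicated block kind
    (e.g. two AAC blocks) raises.
    """
    if not blocks:
        raise ValueError("nothing to fuse")
    kinds: list[str] = []
    for b in blocks:
        kinds.extend(sorted(b.block_kinds()))
    if len(kinds) != len(set(kinds)):
        raise ValueError(f"duplicate block kinds in fusion: {sorted(kinds)}")
    lam = next((b.lam for b in blocks if b.lam is not None), None)
    return FeatureVector(
        np.concatenate([b.components for b in blocks]),
        tuple(n for b in blocks for n in b.names),
        lam=lam,
    )


@dataclass(frozen=True)
class FeatureSpec:
    """Which blocks a classifier sees, and the encoder settings for acACS."""

    acacs: bool = True
    aac: bool = True
    dc: bool = True
    atoms: tuple[str, ...] = ATOM_ORDER
    lam_max: int = 12
    missing_policy: str = "cell_row_mean"

    def describe(self) -> str:
        parts = []
        if self.acacs:
            parts.append(f"acACS(atoms={'+'.join(self.atoms)}, lam={self.lam_max})")
        if self.aac:
            parts.append("AAC")
        if self.dc:
            parts.append("DC")
        return " + ".join(parts) if parts else "(empty)"


def encode_sample(sample: ProteinSample, table: AcsTable | None,
                  spec: FeatureSpec) -> FeatureVector:
    """Encode one sample under a :class:`FeatureSpec` (fusing its blocks)."""
    blocks: list[FeatureVector] = []
    if spec.acacs:
        if table is None:
            raise ValueError("acACS block requested but no ACS table supplied")
        blocks.append(
            encode_acacs(sample, table, spec.atoms, spec.lam_max, spec.missing_policy)
        )
    if spec.aac:
        blocks.append(aac(sample.sequence))
    if spec.dc:
        blocks.append(dc(sample.sequence))
    if not blocks:
        raise ValueError("feature spec selects no blocks")
    return fuse(blocks)


def encode_dataset(
    samples: list[ProteinSample], table: AcsTable | None, spec: FeatureSpec
) -> pd.DataFrame:
    """Feature matrix: one row per protein, named columns, id as the index."""
    rows = []
    index = []
    names: tuple[str, ...] | None = None
    for sample in samples:
        vec = encode_sample(sample, table, spec)
        if names is None:
            names = vec.names
        elif vec.names != names:
            raise ValueError(f"{sample.protein_id}: inconsistent feature layout")
        rows.append(vec.components)
        index.append(sample.protein_id)
    return pd.DataFrame(np.vstack(rows), index=pd.Index(index, name="protein_id"),
                        columns=list(names))
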