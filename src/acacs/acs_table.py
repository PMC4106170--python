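"""Averaged-chemical-shift (ACS) reference tables.

For backbone atom ``i``, residue type ``j`` and secondary-structure state
``k``, the ACS is the arithmetic mean of every assigned shift routed to that
cell:

    C_k^i(j) = (1/N) * sum of the N observed shifts omega_k^i(j)

pooled over all proteins in the corpus.  A full table is the 4 x 20 x 3 grid
of such cells (240 cells); cells with no observations — notably the proline
amide-proton cells, since proline has no backbone H_N — are kept and flagged
missing rather than dropped.

The module also provides the corpus-curation steps that precede the build:
a minimum-length / matched-annotation filter and a greedy sequence-identity
screen, plus a lossless TSV serialisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .alphabets import AA_ORDER, ATOM_ORDER, SS_ORDER, check_atom, check_residue, check_ss
from .star_io import ProteinSample, ShiftObservation

TABLE_COLUMNS = ("atom", "residue", "ss", "mean_ppm", "count", "sd_ppm")


@dataclass(frozen=True)
class AcsCell:
    """One (atom, residue, SS) cell: the mean shift, its count and spread."""

    atom: str
    residue: str
    ss: str
    mean_ppm: float  # NaN when count == 0
    count: int
    sd_ppm: float  # sample SD; 0 when count == 1, NaN when count == 0

    @property
    def missing(self) -> bool:
        return self.count == 0


class AcsTable:
    """The complete 240-cell grid of averaged chemical shifts."""

    def __init__(self, frame: pd.DataFrame, provenance: str = ""):
        frame = frame.copy()
        missing_cols = set(TABLE_COLUMNS) - set(frame.columns)
        if missing_cols:
            raise ValueError(f"table frame missing columns {sorted(missing_cols)}")
        key = list(zip(frame["atom"], frame["residue"], frame["ss"]))
        if len(set(key)) != len(key):
            dupes = pd.Series(key)[pd.Series(key).duplicated()].unique()
            raise ValueError(f"duplicate table keys: {list(dupes)[:5]}")
        frame = frame.set_index(["atom", "residue", "ss"])
        # complete the grid: absent keys become flagged-missing cells
        full_index = pd.MultiIndex.from_product(
            [ATOM_ORDER, list(AA_ORDER), SS_ORDER], names=["atom", "residue", "ss"]
        )
        frame = frame.reindex(full_index)
        frame["count"] = frame["count"].fillna(0).astype(int)
        self._frame = frame[["mean_ppm", "count", "sd_ppm"]]
        self.provenance = provenance

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying (atom, residue, ss)-indexed DataFrame (read-only view)."""
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)

    def cell(self, atom: str, residue: str, ss: str) -> AcsCell:
        check_atom(atom), check_residue(residue), check_ss(ss)
        row = self._frame.loc[(atom, residue, ss)]
        return AcsCell(atom, residue, ss, float(row["mean_ppm"]), int(row["count"]),
                       float(row["sd_ppm"]))

    def mean(self, atom: str, residue: str, ss: str) -> float:
        """Cell mean in ppm; NaN when the cell is missing."""
        return float(self._frame.at[(atom, residue, ss), "mean_ppm"])

    def missing_cells(self) -> list[tuple[str, str, str]]:
        mask = self._frame["count"] == 0
        return [tuple(k) for k in self._frame.index[mask]]

    def lookup_grid(self, atom: str) -> pd.DataFrame:
        """20 x 3 mean grid for one atom (residues x SS states)."""
        sub = self._frame.xs(atom, level="atom")["mean_ppm"].unstack("ss")
        return sub.reindex(index=list(AA_ORDER), columns=list(SS_ORDER))


@dataclass
class CurationReport:
    """Counts of what the corpus filters removed, by reason."""

    kept_proteins: int = 0
    removed_short: int = 0
    removed_unmatched: int = 0
    kept_observations: int = 0
    removed_observations: dict[str, int] = field(default_factory=dict)


def curate(
    observations: list[ShiftObservation],
    samples: list[ProteinSample],
    min_length: int = 50,
) -> tuple[list[ShiftObservation], CurationReport]:
    """Drop observations from short or unannotated proteins.

    A protein survives only if it has an SS-annotated sample of length at
    least ``min_length`` (default 50 residues, the conventional cutoff for
    a well-defined fold).  Returns the surviving observations and a report
    counting removals by reason.
    """
    by_id = {s.protein_id: s for s in samples}
    report = CurationReport(removed_observations={"short": 0, "unmatched": 0})
    keep_ids = set()
    seen_ids = {obs.protein_id for obs in observations}
    for pid in seen_ids:
        sample = by_id.get(pid)
        if sample is None:
            report.removed_unmatched += 1
        elif sample.L < min_length:
            report.removed_short += 1
        else:
            keep_ids.add(pid)
    report.kept_proteins = len(keep_ids)
    kept = []
    for obs in observations:
        if obs.protein_id in keep_ids:
            kept.append(obs)
        elif obs.protein_id in by_id:
            report.removed_observations["short"] += 1
        else:
            report.removed_observations["unmatched"] += 1
    report.kept_observations = len(kept)
    return kept, report


def pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Global-alignment identity: exact matches over alignment columns."""
    if aligner is None:
        aligner = _default_aligner()
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def _default_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -0.5
    return aligner


def identity_filter(
    samples: list[ProteinSample], max_identity: float = 0.40
) -> list[ProteinSample]:
    """Greedy longest-first redundancy screen.

    Samples are visited longest first; one is rejected when its global
    alignment identity to any already-retained sample exceeds
    ``max_identity`` (default 40%).  The retained set is returned in the
    original input order.  This is a deliberate simplification of CD-HIT
    style clustering, intended to make the curation pipeline runnable
    end-to-end, not to reproduce CD-HIT's clusters.
    """
    if not samples:
        raise ValueError("identity_filter requires at least one sample")
    aligner = _default_aligner()
    order = sorted(range(len(samples)), key=lambda i: -samples[i].L)
    retained_idx: list[int] = []
    for i in order:
        cand = samples[i]
        if all(
            pairwise_identity(cand.sequence, samples[j].sequence, aligner) <= max_identity
            for j in retained_idx
        ):
            retained_idx.append(i)
    retained_idx.sort()
    return [samples[i] for i in retained_idx]


def build_table(
    observations,
    samples: list[ProteinSample],
    provenance: str = "",
) -> AcsTable:
    """Pool observations into the 240-cell ACS grid.

    Each observation is routed to the cell (atom, residue, SS state at its
    position in the matching sample); cell mean is the pooled arithmetic
    mean, ``sd_ppm`` the sample standard deviation (0 for singleton cells).

    ``observations`` may be a list of :class:`ShiftObservation` or a
    DataFrame with columns protein_id, residue_index, residue, atom,
    shift_ppm.  An observation whose residue letter disagrees with the
    sample, or whose index exceeds the sample length, raises.
    """
    if isinstance(observations, pd.DataFrame):
        obs_df = observations
    else:
        obs_df = pd.DataFrame(
            {
                "protein_id": [o.protein_id for o in observations],
                "residue_index": [o.residue_index for o in observations],
                "residue": [o.residue for o in observations],
                "atom": [o.atom for o in observations],
                "shift_ppm": [o.shift_ppm for o in observations],
            }
        )
    if obs_df.empty:
        raise ValueError("cannot build a table from zero observations")

    by_id = {s.protein_id: s for s in samples}
    seqs = {}
    sss = {}
    for pid, group in obs_df.groupby("protein_id", sort=False):
        sample = by_id.get(pid)
        if sample is None:
            raise ValueError(f"observations reference unknown protein {pid!r}")
        idx = group["residue_index"].to_numpy()
        bad = idx > sample.L
        if bad.any():
            pos = int(idx[bad][0])
            raise ValueError(
                f"{pid}: observation at residue {pos} exceeds sequence length {sample.L}"
            )
        seq_arr = np.frombuffer(sample.sequence.encode(), dtype="S1").astype("U1")
        ss_arr = np.frombuffer(sample.ss.encode(), dtype="S1").astype("U1")
        seqs[pid] = seq_arr
        sss[pid] = ss_arr
        expected = seq_arr[idx - 1]
        mismatch = expected != group["residue"].to_numpy()
        if mismatch.any():
            pos = int(idx[mismatch][0])
            raise ValueError(
                f"{pid}: residue letter disagreement at position {pos} "
                f"(sample has {sample.sequence[pos - 1]!r})"
            )

    # vectorised SS lookup
    ss_col = np.empty(len(obs_df), dtype="U1")
    pid_values = obs_df["protein_id"].to_numpy()
    idx_values = obs_df["residue_index"].to_numpy()
    for pid in seqs:
        mask = pid_values == pid
        ss_col[mask] = sss[pid][idx_values[mask] - 1]
    routed = obs_df.assign(ss=ss_col)
    # canonical summation order makes the build exactly permutation-invariant
    routed = routed.sort_values(
        ["atom", "residue", "ss", "protein_id", "residue_index", "shift_ppm"],
        kind="mergesort",
    )

    grouped = routed.groupby(["atom", "residue", "ss"])["shift_ppm"]
    agg = grouped.agg(mean_ppm="mean", count="size", sd_ppm="std")
    agg["sd_ppm"] = agg["sd_ppm"].fillna(0.0)  # singleton cells
    agg = agg.reset_index()
    return AcsTable(agg, provenance=provenance)


def write_table(table: AcsTable) -> str:
    """Serialise to TSV with full double precision (repr round-trip).

    Fixed row order: atom (N15, C13A, H1A, H1N), residue alphabetical, then
    SS in H, E, C order.  Missing cells are written with empty mean/sd.
    """
    lines = ["\t".join(TABLE_COLUMNS)]
    for atom in ATOM_ORDER:
        for residue in AA_ORDER:
            for ss in SS_ORDER:
                cell = table.cell(atom, residue, ss)
                if cell.missing:
                    mean_s, sd_s = "", ""
                else:
                    mean_s, sd_s = repr(cell.mean_ppm), repr(cell.sd_ppm)
                lines.append(
                    f"{atom}\t{residue}\t{ss}\t{mean_s}\t{cell.count}\t{sd_s}"
                )
    return "\n".join(lines) + "\n"


def read_table(path_or_text, provenance: str = "") -> AcsTable:
    """Parse the TSV serialisation back into an :class:`AcsTable`.

    Duplicate keys raise; keys absent from the file load as flagged-missing
    cells.
    """
    text = path_or_text
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    elif "\n" not in str(path_or_text):
        with open(path_or_text, "r", encoding="utf-8") as handle:
            text = handle.read()
    lines = [ln for ln in str(text).splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if tuple(header) != TABLE_COLUMNS:
        raise ValueError(f"unexpected table header {header}")
    records = []
    for ln in lines[1:]:
        atom, residue, ss, mean_s, count_s, sd_s = ln.split("\t")
        records.append(
            {
                "atom": atom,
                "residue": residue,
                "ss": ss,
                "mean_ppm": float(mean_s) if mean_s else math.nan,
                "count": int(count_s),
                "sd_ppm": float(sd_s) if sd_s else math.nan,
            }
        )
    return AcsTable(pd.DataFrame(records), provenance=provenance)
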