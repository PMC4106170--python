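"""Three-state secondary structure and the 8-state DSSP reduction.

The table statistics and the encoder both work over the coarse alphabet
H (helix), E (strand), C (everything else).  Assignments coming from DSSP
use eight states; the standard reduction groups the helical states
(H, G, I) into H, the extended states (E, B) into E, and maps turns, bends
and unassigned positions to C.  The grouping is configurable for users who
prefer a different convention.
"""

from __future__ import annotations

from .alphabets import SS_SET
from .star_io import ProteinSample

DSSP_ALPHABET = frozenset("HGIEBTS- ")

#: Standard reduction: helical states to H, extended states to E, rest to C.
#: An explicit 'C' (used by some DSSP variants for coil) passes through, so
#: the reduction is idempotent on already-reduced strings.
DEFAULT_8_TO_3: dict[str, str] = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "-": "C", " ": "C", "C": "C",
}


def reduce_8_to_3(dssp_string: str, mapping: dict[str, str] | None = None) -> str:
    """Reduce an 8-state DSSP string to the 3-state H/E/C alphabet.

    Idempotent on strings already over {H, E, C}.  A character outside the
    8-state alphabet raises with its (1-based) position.
    """
    mapping = mapping or DEFAULT_8_TO_3
    out = []
    for pos, ch in enumerate(dssp_string, start=1):
        try:
            out.append(mapping[ch])
        except KeyError:
            raise ValueError(
                f"character {ch!r} at position {pos} is not in the 8-state "
                f"DSSP alphabet {''.join(sorted(DSSP_ALPHABET))!r}"
            ) from None
    return "".join(out)


def validate_ss(ss: str, sequence: str) -> tuple[str, str]:
    """Check that ``ss`` is an H/E/C string aligned with ``sequence``.

    Returns the pair unchanged on success; raises a descriptive error on a
    length mismatch or a symbol outside {H, E, C}.
    """
    if len(ss) != len(sequence):
        raise ValueError(
            f"secondary-structure length {len(ss)} does not match sequence "
            f"length {len(sequence)}"
        )
    for pos, ch in enumerate(ss, start=1):
        if ch not in SS_SET:
            raise ValueError(
                f"secondary-structure symbol {ch!r} at position {pos} is not "
                "one of H/E/C"
            )
    return ss, sequence


def validate_sample(sample: ProteinSample) -> ProteinSample:
    validate_ss(sample.ss, sample.sequence)
    return sample
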