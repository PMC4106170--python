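"""acACS: averaged-chemical-shift tables and autocovariance protein features.

Builds per-(atom, residue, secondary-structure) averaged chemical shift
(ACS) reference tables from assigned backbone NMR shifts, and encodes any
(sequence, secondary structure) pair into a fixed-length feature vector by
replacing residues with their ACS values and summarising the series with
lagged mean-squared differences.  Includes AAC/DC composition features, an
SVM + jackknife evaluation harness with a with/without-acACS ablation, and
a synthetic-data generator for end-to-end testing.
"""

from importlib import resources

from .acs_table import (
    AcsCell,
    AcsTable,
    build_table,
    curate,
    identity_filter,
    read_table,
    write_table,
)
from .alphabets import AA_ORDER, ATOM_ORDER, SS_ORDER
from .features import (
    FeatureSpec,
    FeatureVector,
    ShiftSeries,
    aac,
    autocovariance,
    dc,
    encode_acacs,
    encode_dataset,
    encode_sample,
    fuse,
    lookup_series,
    series_mean,
)
from .model_eval import (
    AblationResult,
    ClassifierConfig,
    EvalReport,
    LabeledDataset,
    ablation,
    jackknife_eval,
)
from .secstruct import reduce_8_to_3, validate_ss
from .star_io import (
    ProteinSample,
    ShiftFileDialect,
    ShiftObservation,
    parse_paired_sequence_ss,
    parse_shift_file,
    write_paired_sequence_ss,
    write_shift_file,
)
from .synthetic import (
    SyntheticDatasetConfig,
    SyntheticShiftConfig,
    default_true_means,
    generate_labeled_dataset,
    generate_shift_corpus,
    no_signal_config,
    ss_only_signal_config,
)

__version__ = "0.1.0"


def example_table() -> AcsTable:
    """The bundled example ACS table (built from a synthetic corpus)."""
    ref = resources.files("acacs").joinpath("data/example_acs_table.tsv")
    return read_table(ref.read_text(), provenance="bundled synthetic example table")
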