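"""netmsa: causal contribution mapping of recurrent networks by perturbation.

Quantifies what each node and connection of a recurrent network contributes
to task performance: single-element perturbation analysis (SPA),
multi-perturbation Shapley-value analysis (MSA) with a permutation-sampling
estimator, pairwise causal interaction analysis (PCIA) with paradoxical-
lesion (Sprague-effect) detection, lesion impact on functional connectivity
(IFC), and mean-shifted bootstrap significance testing.  A bundled synthetic
ground-truth network contains an inhibitory self-loop motif that produces a
paradoxical lesion effect.
"""

from importlib import resources

from .netmodel import (
    ActivityTrace,
    CapacityError,
    ConfigurationError,
    ConnectionGene,
    EMPTY_MASK,
    Genome,
    LesionMask,
    NetworkState,
    NodeGene,
    ValidationError,
    mask_connections,
    node_lesion_mask,
    prune_disabled,
    register_activation,
    register_aggregation,
    run,
    step,
)
from .toytask import (
    CanonicalGame,
    InputSeries,
    ProtocolSpec,
    TaskSpec,
    canonical_games,
    generate_inputs,
    make_motif_genome,
    noise_input_control,
    run_protocol,
    score_episode,
    weight_shuffle_control,
)
from .shapley import (
    CoalitionGame,
    ShapleyTable,
    SPAResult,
    exact_shapley,
    lesion_game,
    marginal_contribution,
    rank_table,
    sampled_shapley,
    shapley_fraction,
    spa,
)
from .pcia import (
    InteractionMatrix,
    PairAnalysis,
    SpragueEdge,
    compound_game,
    conditioned_game,
    detect_sprague,
    interaction_matrix,
    interaction_term,
    pair_analysis,
    threshold_pairs,
)
from .fcanalysis import FCMatrix, correlate_ifc, fc, ifc, ifc_sweep
from .stats import (
    BootstrapResult,
    bonferroni_alpha,
    bootstrap_p,
    percentile_ci,
    ranksum,
    significance_report,
)

__version__ = "0.1.0"


def motif_genome_path() -> str:
    """Filesystem path of the bundled motif genome JSON."""
    return str(resources.files("netmsa").joinpath("data/motif_genome.json"))
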