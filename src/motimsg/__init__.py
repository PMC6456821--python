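"""motimsg: situation-based motivational messages for PTSD e-therapy.

The package implements a message-composition system conditioned on a
patient's situation (brief-PCL symptom trend x initial trust in a good
therapy outcome), the expert-corpus pipeline that derives its probability,
length and statement tables, and the statistical machinery of its
evaluation study — all exercisable end to end on synthetic data with known
ground truth.
"""

from importlib import resources

from .situations import (
    Trend,
    Trust,
    Situation,
    enumerate_situations,
    classify_trend,
    score_brief_pcl,
)
from .database import (
    StatementDatabase,
    Statement,
    StatementType,
    load_database,
    save_database,
    validate,
    leaves,
    statements_for,
)
from .generate import (
    GeneratedMessage,
    SelectionTrace,
    compose_message,
    select_types,
    order_types,
    target_length,
    mandatory_types,
    weighted_select,
    resolve_supertype,
)
from .corpus import (
    CodedAnswer,
    build_occurrence,
    filter_types,
    fit_type_model,
    derive_probability_table,
    derive_length_table,
    retain_statements,
    cohens_kappa,
    lrt,
)
from .study import (
    anova_power_n,
    anova_power,
    one_sample_t,
    cronbach_alpha,
    fit_ladder,
    posthoc_pairwise,
)
from .simulate import (
    ExpertSimSpec,
    StudySimSpec,
    make_default_database,
    simulate_expert_corpus,
    simulate_user_study,
)

__version__ = "0.1.0"


def default_database_path() -> str:
    """Filesystem path of the bundled synthetic database JSON."""
    return str(resources.files("motimsg").joinpath("data/default_database.json"))
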