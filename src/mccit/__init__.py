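"""Minimal biomarker-signature selection for multi-class outcomes.

Continuous features (e.g. normalized gene expression), a nominal or ordinal
class outcome, and a constraint-based selection algorithm (MMPC) driven by a
conditional independence test built for exactly this data shape: a
log-likelihood-ratio comparison of nested multinomial-logit or ordered-logit
models.  Fisher-Z and G-squared reference tests, ground-truth synthetic
generators, and a nested cross-validation benchmarking protocol round out
the toolkit.
"""

from .cit import (
    CITConfig,
    CITResult,
    FisherZ,
    G2,
    MCCIT,
    discretize_three_bins,
    fisher_z_cit,
    g2_cit,
    make_cit,
    mc_cit,
)
from .data import LabeledDataset
from .evaluation import (
    EvaluationReport,
    FoldPlan,
    MethodGrid,
    accuracy,
    compare_feature_counts,
    exact_binomial_compare,
    make_fold_plan,
    nested_cv,
    trivial_classifier,
)
from .glm import (
    MultinomialLogit,
    MultinomialLogitResults,
    OrderedLogit,
    OrderedLogitResults,
    fit_multinomial_logit,
    fit_ordered_logit,
    predict_proba,
)
from .io import TableSpec, read_dataset, write_dataset
from .mmpc import MMPC, AssocCache, MMPCConfig, MMPCResult, min_assoc, mmpc
from .synthetic import (
    DSeparationOracle,
    GroundTruth,
    gen_bn_fixture,
    gen_categorical_dataset,
    gen_null_triplet,
    gen_ordinal_dataset,
    toy_bn_fixture,
)

__version__ = "0.1.0"

__all__ = [name for name in dir() if not name.startswith("_")]
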