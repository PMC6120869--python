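"""Weakly-supervised classification of H&E tissue-microarray cores.

Two-stage multiple-instance pipeline: calibrated linear-SVM ensembles
score 800x800-pixel tissue regions, region probabilities are pooled into
a 16-value quantile signature per patient, and a second calibrated SVM
with task-specific cut points yields the patient-level call for tumor
grade, ER status, Basal-like subtype, histologic subtype and ROR risk
class — plus the concordance statistics used to compare those calls
against pathologist or molecular reference labels.
"""

from .aggregate import (
    CutPoints,
    QuantileSignature,
    TrainedPipeline,
    classify,
    fit_patient_model,
    predict_core,
    predict_patient,
    quantile_signature,
    select_cut_point,
)
from .evaluate import (
    ConfusionSummary,
    chi_square_homogeneity,
    cohens_kappa,
    confusion,
    odds_ratio,
    percent_agreement,
    rates,
    summarize,
)
from .features import ExtractorSpec, extract_feature_map, filterbank_features, pool_region_features
from .instance_model import (
    InstanceEnsemble,
    compute_sample_weights,
    fit_instance_ensemble,
    predict_instance_prob,
)
from .preprocess import (
    NoTissueError,
    RegionGrid,
    StainNormalizedImage,
    StainReference,
    extract_regions,
    normalize_stains,
    tissue_mask,
)
from .synthetic_cohort import (
    CohortConfig,
    FeatureBag,
    PatientRecord,
    generate_cohort,
    synthesize_core_image,
    synthesize_feature_bag,
)
from .workflow import RunConfig, render_heatmap, run_pipeline

__version__ = "0.1.0"
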