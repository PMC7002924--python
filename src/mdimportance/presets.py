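"""Analysis presets for the three published case studies.

Each preset bundles a featurization recipe, its distance filters (nm),
the estimator hyperparameters, and the cross-validation/iteration counts
used for that system.  They assume the user supplies the corresponding
trajectory and label table; none of the external data ships with the
package.

cam   Calmodulin C-terminal domain, six states: inverse Calpha distances,
      1.0 nm contact-change filter, block shuffling (100 frames), PCA at
      75% cumulative variance, AE/MLP hidden layers (120, 100), RF with
      500 trees one-vs-rest, 3-fold CV, 5 iterations.
gpcr  beta2 adrenergic receptor, ligand-bound vs unbound: inverse Calpha
      distances over all residues, PCA eigengap criterion (order of
      magnitude), RF with 1000 trees, 4-fold CV, 30 iterations.
vsd   Kv1.2 voltage-sensor domain, five metastable states: inverse
      closest-heavy-atom residue distances, 0.5-0.7 nm range filter, RF
      with 100 trees, 3-fold CV, 5 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .extractors import ExtractorSpec

__all__ = ["AnalysisPreset", "PRESETS"]


@dataclass(frozen=True)
class AnalysisPreset:
    name: str
    scheme: str  # mdtraj contact scheme: 'ca' or 'closest-heavy'
    contact_change_cutoff_nm: float | None = None
    range_filter_nm: tuple[float, float] | None = None
    block_shuffle_size: int | None = None
    methods: dict = field(default_factory=dict)
    n_folds: int = 3
    n_iterations: int = 5


PRESETS: dict[str, AnalysisPreset] = {
    "cam": AnalysisPreset(
        name="cam",
        scheme="ca",
        contact_change_cutoff_nm=1.0,
        block_shuffle_size=100,
        methods={
            "PCA": ExtractorSpec("PCA", {"criterion": ("cumulative_variance", 0.75)}),
            "RBM": ExtractorSpec("RBM", {}),
            "AE": ExtractorSpec("AE", {"hidden_layers": (120, 100, 120)}),
            "KL": ExtractorSpec("KL", {}),
            "RF": ExtractorSpec("RF", {"n_estimators": 500, "mode": "one_vs_rest"}),
            "MLP": ExtractorSpec("MLP", {"hidden_layers": (120, 100)}),
        },
        n_folds=3,
        n_iterations=5,
    ),
    "gpcr": AnalysisPreset(
        name="gpcr",
        scheme="ca",
        methods={
            "PCA": ExtractorSpec("PCA", {"criterion": ("eigengap", 10.0)}),
            "RF": ExtractorSpec("RF", {"n_estimators": 1000}),
        },
        n_folds=4,
        n_iterations=30,
    ),
    "vsd": AnalysisPreset(
        name="vsd",
        scheme="closest-heavy",
        range_filter_nm=(0.5, 0.7),
        methods={
            "RF": ExtractorSpec("RF", {"n_estimators": 100}),
        },
        n_folds=3,
        n_iterations=5,
    ),
}
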