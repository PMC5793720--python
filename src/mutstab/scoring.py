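"""Pseudo-ddG stability difference scoring.

The score for a mutation j -> k is the four-term decomposition

    dds = ds_unfolded - ds_folded - (ds_disrupt + ds_cavity)

where the first two terms are symmetrized conservation log-odds computed
from substitution tables -- ds_folded in the wildtype and mutant-model
structural environments, ds_unfolded on the environment-marginal
("unfolded state") table -- and the two penalties capture structural
strain that substitution statistics alone miss:

* a disruption penalty, log(1 + |dA_sc| / 100 A^2), for a net change in
  absolute sidechain accessible area at the site;
* a cavity penalty, active only when a buried (RSA < 17%) Phe/Leu/Ile is
  replaced by Ala or Val, log(1 + |dOSP| / 0.33) scaled by a weight,
  where 0.33 is the mean packing of solvent-exposed regions.

Positive dds is read as stabilising, negative as destabilising.  The
scores are in natural-log units; they are not calibrated to kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import (
    Annotator,
    EnvironmentAnnotation,
    EnvironmentClassIndex,
    EnvironmentConfig,
    classify_environment,
)
from .errors import ConfigError
from .esst import ESSTSet
from .sidechain import build_mutant_model
from .structure import MutationSpec, ProteinStructure

__all__ = [
    "ScoreWeights",
    "ScoreBreakdown",
    "PredictionRecord",
    "delta_s_folded",
    "delta_s_unfolded",
    "disruption_penalty",
    "cavity_penalty",
    "predict",
    "predict_reverse",
]

CAVITY_WT = frozenset("FLI")
CAVITY_MUT = frozenset("AV")
EXPOSED_MEAN_OSP = 0.33
DISRUPT_AREA_SCALE = 100.0  # A^2


@dataclass(frozen=True)
class ScoreWeights:
    """Penalty weights; the cavity weight is the calibration knob."""

    disrupt: float = 1.0
    cavity: float = 2.0


@dataclass(frozen=True)
class ScoreBreakdown:
    ds_unfolded: float
    ds_folded: float
    ds_disrupt: float
    ds_cavity: float

    @property
    def dds(self) -> float:
        return self.ds_unfolded - self.ds_folded - (self.ds_disrupt + self.ds_cavity)

    @property
    def classification(self) -> str:
        return "stabilising" if self.dds > 0 else "destabilising"


@dataclass
class PredictionRecord:
    mutation: MutationSpec
    breakdown: ScoreBreakdown
    wt_env: EnvironmentAnnotation
    mut_env: EnvironmentAnnotation
    wt_class: EnvironmentClassIndex
    mut_class: EnvironmentClassIndex
    direction: str = "forward"
    mutant_model: ProteinStructure | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def dds(self) -> float:
        return self.breakdown.dds

    @property
    def classification(self) -> str:
        return self.breakdown.classification

    def to_row(self) -> dict:
        b = self.breakdown
        return {
            "mutation": str(self.mutation),
            "chain": self.mutation.chain_id,
            "direction": self.direction,
            "dds": round(b.dds, 4),
            "ds_unfolded": round(b.ds_unfolded, 4),
            "ds_folded": round(b.ds_folded, 4),
            "ds_disrupt": round(b.ds_disrupt, 4),
            "ds_cavity": round(b.ds_cavity, 4),
            "classification": self.classification,
            "wt_mainchain": self.wt_env.mainchain_label,
            "wt_rsa": round(self.wt_env.rsa, 2),
            "wt_osp": round(self.wt_env.osp, 4),
            "wt_depth": round(self.wt_env.depth, 3),
            "wt_hbond_class": self.wt_env.hbond_class,
            "wt_env": self.wt_class.label,
            "mut_mainchain": self.mut_env.mainchain_label,
            "mut_rsa": round(self.mut_env.rsa, 2),
            "mut_osp": round(self.mut_env.osp, 4),
            "mut_depth": round(self.mut_env.depth, 3),
            "mut_hbond_class": self.mut_env.hbond_class,
            "mut_env": self.mut_class.label,
            "mutant_model": self.metadata.get("mutant_model_path", ""),
        }


def _log_odds(pjj: float, pkj: float, pkk: float, pjk: float) -> float:
    for p in (pjj, pkj, pkk, pjk):
        if p <= 0:
            raise ConfigError("zero substitution probability; tables unsmoothed?")
    return 0.5 * (np.log(pjj / pkj) + np.log(pkk / pjk))


def delta_s_folded(
    essts: ESSTSet, j: str, k: str, env_wt: int, env_mut: int
) -> float:
    """Folded-state stability score difference for j -> k.

    Symmetrized log-odds of conserving the wildtype versus accepting the
    mutant, evaluated in the wildtype structure's environment and the
    mutant model's environment; large values mean the environments are
    intolerant of the substitution.
    """
    return _log_odds(
        essts.p(env_wt, j, j),
        essts.p(env_wt, j, k),
        essts.p(env_mut, k, k),
        essts.p(env_mut, k, j),
    )


def delta_s_unfolded(essts: ESSTSet, j: str, k: str) -> float:
    """Unfolded-state score difference: same form on the marginal table."""
    return _log_odds(
        essts.p_unfolded(j, j),
        essts.p_unfolded(j, k),
        essts.p_unfolded(k, k),
        essts.p_unfolded(k, j),
    )


def disruption_penalty(
    annotation_wt: EnvironmentAnnotation,
    annotation_mut: EnvironmentAnnotation,
    weight_d: float = 1.0,
) -> float:
    """Penalty for the net change in absolute sidechain accessible area."""
    delta = abs(annotation_wt.sidechain_area - annotation_mut.sidechain_area)
    return weight_d * float(np.log1p(delta / DISRUPT_AREA_SCALE))


def cavity_penalty(
    mutation: MutationSpec,
    annotation_wt: EnvironmentAnnotation,
    annotation_mut: EnvironmentAnnotation,
    weight_c: float = 2.0,
    buried_rsa: float = 17.0,
) -> float:
    """Void-creation penalty for buried bulky-hydrophobic -> small.

    Fires only for F/L/I -> A/V at sites with wildtype RSA below the
    buried cutoff; scales with the OSP change relative to the mean OSP of
    solvent-exposed regions (0.33).
    """
    if mutation.wt_aa not in CAVITY_WT or mutation.mut_aa not in CAVITY_MUT:
        return 0.0
    if annotation_wt.rsa >= buried_rsa:
        return 0.0
    delta = abs(annotation_wt.osp - annotation_mut.osp)
    return weight_c * float(np.log1p(delta / EXPOSED_MEAN_OSP))


def predict(
    structure: ProteinStructure,
    mutation: MutationSpec,
    essts: ESSTSet,
    config: EnvironmentConfig | None = None,
    weights: ScoreWeights | None = None,
    direction: str = "forward",
    keep_model: bool = True,
    wt_annotator: Annotator | None = None,
) -> PredictionRecord:
    """Score a point mutation on a structure.

    Builds the mutant model, annotates the site in both structures,
    evaluates the four score terms and classifies by the sign of dds.
    Deterministic for fixed inputs.  ``wt_annotator`` lets callers reuse
    the wildtype structure's geometry across a batch of mutations.
    """
    config = config or essts.config
    if config.scheme != essts.config.scheme:
        raise ConfigError(
            f"config scheme {config.scheme} does not match ESST scheme "
            f"{essts.config.scheme}"
        )
    weights = weights or ScoreWeights()

    model = build_mutant_model(structure, mutation)
    site_id = (mutation.chain_id, mutation.seq_number, mutation.insertion_code)

    ann_wt = wt_annotator or Annotator(structure, config)
    ann_mut = Annotator(model, config)
    wt_res = structure.get_residue(*site_id)
    mut_res = model.get_residue(*site_id)
    wt_env = ann_wt.annotate(wt_res)
    mut_env = ann_mut.annotate(mut_res)
    wt_class = classify_environment(wt_env, config)
    mut_class = classify_environment(mut_env, config)

    j, k = mutation.wt_aa, mutation.mut_aa
    ds_u = delta_s_unfolded(essts, j, k)
    ds_f = delta_s_folded(essts, j, k, wt_class.index, mut_class.index)
    ds_d = disruption_penalty(wt_env, mut_env, weights.disrupt)
    ds_c = cavity_penalty(
        mutation, wt_env, mut_env, weights.cavity, config.buried_rsa
    )
    return PredictionRecord(
        mutation=mutation,
        breakdown=ScoreBreakdown(ds_u, ds_f, ds_d, ds_c),
        wt_env=wt_env,
        mut_env=mut_env,
        wt_class=wt_class,
        mut_class=mut_class,
        direction=direction,
        mutant_model=model if keep_model else None,
        metadata={"scheme": config.scheme,
                  "mutant_protocol": model.metadata.get("mutant_protocol", "")},
    )


def predict_reverse(
    wildtype: ProteinStructure,
    mutation: MutationSpec,
    essts: ESSTSet,
    config: EnvironmentConfig | None = None,
    weights: ScoreWeights | None = None,
) -> PredictionRecord:
    """Score the hypothetical reverse mutation k -> j.

    The mutant model is built first, then scored with the inverted
    mutation at the same site.  Note the conservation log-odds is
    symmetric under exchanging (wildtype, wildtype environment) with
    (mutant, mutant environment), so the table terms of a reverse score
    echo the forward ones when modelling is exact; the penalties are
    direction-specific (the cavity term only fires bulky -> small), which
    is what differentiates reverse predictions in practice.
    """
    model = build_mutant_model(wildtype, mutation)
    return predict(
        model, mutation.inverted(), essts, config, weights, direction="reverse"
    )
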