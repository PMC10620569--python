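"""Per-species model sets and CPO-based model selection.

Every species gets 10 competing models: {full, reduced} parameterizations
crossed with occupancy forms {null, season, pca, season+pca, season*pca}.
Mesocarnivores get 4 more: {full, reduced} x {prey, prey+season}.  Models are
ranked by the CPO score (sum of negative log conditional predictive
ordinates; lower = better predictive support).  Non-converged fits are
excluded from the ranking; scores within 0.01 of each other are treated as
tied and the reduced (more parsimonious) parameterization wins the tie.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .covariates import assemble_design
from .model import MSDOM

BASE_FORMS = ("null", "season", "pca", "season+pca", "season*pca")
PREY_FORMS = ("prey", "prey+season")
TIE_TOLERANCE = 0.01


@dataclass(frozen=True)
class ModelSpec:
    parameterization: str
    form: str

    @property
    def label(self) -> str:
        return f"{self.parameterization}:{self.form}"


def standard_model_set(mesocarnivore: bool = False) -> list[ModelSpec]:
    forms = BASE_FORMS + (PREY_FORMS if mesocarnivore else ())
    return [ModelSpec(p, f) for f in forms for p in ("full", "reduced")]


def run_model_set(
    history: pd.DataFrame,
    pca: pd.Series | None = None,
    prey: pd.DataFrame | None = None,
    model_set: list[ModelSpec] | None = None,
    mcmc: dict | None = None,
):
    """Fit every model in the set and rank by CPO score.

    Returns (ranking DataFrame sorted by score, best MSDOMResults).  Raises
    if no model converges.
    """
    model_set = standard_model_set() if model_set is None else model_set
    mcmc = dict(mcmc or {})
    results = {}
    rows = []
    for spec in model_set:
        design = assemble_design(history.index, pca=pca, prey=prey, form=spec.form)
        model = MSDOM(history, design, parameterization=spec.parameterization)
        res = model.fit(label=spec.label, **mcmc)
        results[spec.label] = res
        rows.append({
            "model": spec.label,
            "parameterization": spec.parameterization,
            "form": spec.form,
            "cpo_score": res.cpo_score,
            "converged": res.converged,
            "max_rhat": float(res.rhat.max()),
        })
    ranking = pd.DataFrame(rows).sort_values("cpo_score", kind="stable").reset_index(drop=True)
    best_label = select_best(ranking)
    return ranking, results[best_label]


def select_best(ranking: pd.DataFrame, tie_tolerance: float = TIE_TOLERANCE) -> str:
    """Best model label: lowest CPO score among converged fits.

    Within ``tie_tolerance`` of the lowest score, a reduced parameterization
    is preferred over a full one (parsimony tie-break).
    """
    conv = ranking[ranking["converged"]]
    if conv.empty:
        raise RuntimeError("no model in the set converged")
    if len(conv) < len(ranking):
        warnings.warn(
            f"{len(ranking) - len(conv)} non-converged model(s) excluded from ranking"
        )
    best_score = conv["cpo_score"].min()
    tied = conv[conv["cpo_score"] <= best_score + tie_tolerance]
    reduced = tied[tied["parameterization"] == "reduced"]
    pick = reduced if not reduced.empty else tied
    return pick.sort_values("cpo_score", kind="stable").iloc[0]["model"]
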