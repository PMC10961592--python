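"""End-to-end analysis: tidy dialysate tables in, parameter tables out.

Pipeline order mirrors the experimental workflow: probe recovery ->
concentration correction -> NCA -> compartmental PK fitting and selection
-> baseline normalisation -> effect-compartment link fitting -> hysteresis
classification. Fitting operates on group-mean profiles (time-averaged
concentration and effect values), the standard mode for sparse
microdialysis designs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compartmental import PkFit, fit_pk, select_model
from .link import (LinkFit, classify_relationship, fit_link, hysteresis_loop)
from .nca import NcaResult, nca_full
from .pdmodels import normalize_effect
from .recovery import (RecoveryTable, compute_recovery, recovery_from_frame,
                       select_flow_rate)
from .series import SampleSeries, group_mean_series

__all__ = ["PipelineResult", "analyze_experiment", "DEFAULT_NT_MODES"]

#: default response direction per neurotransmitter: excitatory transmitters
#: are suppressed by treatment, the others enhanced
DEFAULT_NT_MODES = {"Asp": "inhibition", "Glu": "inhibition",
                    "Tau": "stimulation", "Ach": "stimulation"}


@dataclass
class PipelineResult:
    flow_rate: float | None
    recovery_table: RecoveryTable | None
    analyte_recovery: dict[str, float]
    nca: dict[tuple[str, str], NcaResult]          # (lignan, group)
    pk_fits: dict[tuple[str, str], PkFit]
    link_fits: dict[tuple[str, str], LinkFit]      # (neurotransmitter, group)
    hysteresis: pd.DataFrame = field(default_factory=pd.DataFrame)

    def nca_frame(self) -> pd.DataFrame:
        rows = []
        for (analyte, group), res in self.nca.items():
            rows.append({"analyte": analyte, "group": group,
                         **{k: v for k, v in res.to_dict().items()
                            if k not in ("analyte", "subject")}})
        return pd.DataFrame(rows)

    def pk_frame(self) -> pd.DataFrame:
        rows = []
        for (analyte, group), fit in self.pk_fits.items():
            rows.append({"analyte": analyte, "group": group,
                         "model_id": fit.model_id, **fit.params.as_dict(),
                         "aic": fit.scores.aic, "bic": fit.scores.bic})
        return pd.DataFrame(rows)

    def link_frame(self) -> pd.DataFrame:
        rows = []
        for (nt, group), fit in self.link_fits.items():
            rows.append({"neurotransmitter": nt, "group": group,
                         **fit.params.as_dict(), "aic": fit.scores.aic})
        return pd.DataFrame(rows)


def analyze_experiment(lignans: pd.DataFrame, neurotransmitters: pd.DataFrame,
                       recovery_raw: pd.DataFrame | None = None, *,
                       index_lignan: str = "schisandrol A",
                       nt_modes: dict[str, str] | None = None,
                       interval: float | None = 20.0,
                       baseline_window: tuple[float, float] = (-20.0, 0.0),
                       correct_for_recovery: bool = True,
                       models: tuple[str, ...] = ("1C", "2C"),
                       dose: float = 100.0,
                       seed: int = 0) -> PipelineResult:
    """Run the full analysis on tidy lignan/neurotransmitter tables.

    When a raw in-vitro recovery table is supplied, the operating flow rate
    is selected by maximal mean recovery and (optionally) all lignan
    concentrations are corrected by the analyte's mean recovery at that
    rate before PK analysis. PD fitting always uses the effect-compartment
    route: the index lignan's selected PK fit drives each
    neurotransmitter's normalised response.
    """
    nt_modes = dict(DEFAULT_NT_MODES, **(nt_modes or {}))

    flow = None
    rec_table = None
    analyte_recovery: dict[str, float] = {}
    if recovery_raw is not None:
        rec_table = compute_recovery(recovery_from_frame(recovery_raw))
        flow = select_flow_rate(rec_table)
        at_flow = rec_table.by_flow[rec_table.by_flow["flow_rate"] == flow]
        analyte_recovery = dict(zip(at_flow["analyte"],
                                    at_flow["mean_recovery"]))

    nca_out: dict[tuple[str, str], NcaResult] = {}
    pk_out: dict[tuple[str, str], PkFit] = {}
    groups = sorted(lignans["group"].unique())
    for analyte in sorted(lignans["analyte"].unique()):
        for group in groups:
            s = group_mean_series(lignans, analyte, group, interval=interval,
                                  baseline_window=baseline_window)
            if correct_for_recovery and analyte in analyte_recovery:
                s = s.scaled(1.0 / analyte_recovery[analyte])
            nca_out[(analyte, group)] = nca_full(s)
            fits = [fit_pk(s, m, dose=dose, seed=seed) for m in models]
            pk_out[(analyte, group)] = select_model(fits)

    link_out: dict[tuple[str, str], LinkFit] = {}
    hyst_rows = []
    for nt in sorted(neurotransmitters["analyte"].unique()):
        mode = nt_modes.get(nt, "stimulation")
        for group in sorted(neurotransmitters["group"].unique()):
            raw = group_mean_series(neurotransmitters, nt, group,
                                    interval=interval,
                                    baseline_window=baseline_window)
            effect = normalize_effect(raw)
            pk_fit = pk_out[(index_lignan, group)]
            conc_series = group_mean_series(lignans, index_lignan, group,
                                            interval=interval,
                                            baseline_window=baseline_window)
            lf = fit_link(conc_series, effect, pk_fit, mode, seed=seed)
            link_out[(nt, group)] = lf

            # observed loop: measured driver concentration vs measured effect
            post = effect.post_dose()
            conc_post = conc_series.post_dose()
            shared = np.intersect1d(post.times, conc_post.times)
            c = conc_post.concentrations[np.isin(conc_post.times, shared)]
            e = post.effect[np.isin(post.times, shared)]
            loop = hysteresis_loop(c, e, shared)
            hyst_rows.append({
                "neurotransmitter": nt, "group": group, "mode": mode,
                "lignan": index_lignan,
                "signed_area": loop.signed_area,
                "normalized_area": loop.normalized_area,
                "direction": loop.direction,
                "label": classify_relationship(loop, mode),
            })
    return PipelineResult(flow, rec_table, analyte_recovery, nca_out, pk_out,
                          link_out, pd.DataFrame(hyst_rows))
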