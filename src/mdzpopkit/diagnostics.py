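"""Visual predictive checks and goodness-of-fit residual summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .datasim import StudyDesign, observation_rows, simulate_dataset
from .estimation import prepare_dataset, _SubjectLikelihood
from .parameters import (
    PopulationParameters,
    RandomEffectsSpec,
    TreatmentEffects,
)

__all__ = ["VpcSummary", "run_vpc", "compute_residuals"]

_PCTL = (2.5, 50.0, 97.5)
_BAND = (5.0, 95.0)  # 90% simulation interval for each percentile
_NORM_DOSE_MG = 4.0


@dataclass
class VpcSummary:
    """Percentile bands of a visual predictive check.

    ``table`` has one row per (arm, analyte, time bin) with the observed
    2.5/50/97.5 percentiles of dose-normalized concentration and the 90%
    simulation interval for each percentile; ``n_sim`` replicate trials
    were simulated under the fitted model.
    """

    table: pd.DataFrame
    n_sim: int
    norm_dose_mg: float = _NORM_DOSE_MG

    def median_coverage(self) -> float:
        """Fraction of bins whose observed median lies in the simulated
        90% interval for the median."""
        t = self.table
        ok = (t["obs_p50"] >= t["sim_p50_lo"]) & (t["obs_p50"] <= t["sim_p50_hi"])
        return float(ok.mean())


def _occasion_dose_mg(table: pd.DataFrame) -> pd.Series:
    """Total midazolam dose (mg) of each (ID, OCC), for dose normalization."""
    doses = table[table["EVID"] == 1].groupby(["ID", "OCC"])["AMT"].sum()
    return doses


def _normalized_obs(table: pd.DataFrame, norm_mg: float) -> pd.DataFrame:
    obs = observation_rows(table).copy()
    dose = _occasion_dose_mg(table)
    key = pd.MultiIndex.from_frame(obs[["ID", "OCC"]])
    obs["DVN"] = obs["DV"].to_numpy() * norm_mg / dose.loc[key].to_numpy()
    return obs


def _bin_percentiles(obs: pd.DataFrame, min_per_bin: int = 3) -> pd.DataFrame:
    """Observed percentiles per (arm, analyte, nominal time).

    Sampling times are protocol-fixed, so bins are the nominal times
    themselves; undersized bins are merged into the nearest neighbor.
    """
    rows = []
    for (trt, cmt), grp in obs.groupby(["TRT", "CMT"]):
        times = np.sort(grp["TIME"].unique())
        merged: list[list[float]] = []
        for t in times:
            count = int((grp["TIME"] == t).sum())
            if merged and count < min_per_bin:
                warnings.warn(f"bin {trt}/{cmt}@{t} h has < {min_per_bin} obs; merged")
                merged[-1].append(t)
            else:
                merged.append([t])
        for bin_times in merged:
            sel = grp[grp["TIME"].isin(bin_times)]
            p = np.percentile(sel["DVN"], _PCTL)
            rows.append(
                dict(TRT=trt, CMT=cmt, time=float(np.median(bin_times)),
                     bin_times=tuple(bin_times), n=len(sel),
                     p2_5=p[0], p50=p[1], p97_5=p[2])
            )
    return pd.DataFrame(rows)


def run_vpc(
    data: pd.DataFrame,
    design: StudyDesign,
    pop: PopulationParameters,
    re: RandomEffectsSpec,
    effects_map: Mapping[str, TreatmentEffects],
    n_sim: int = 1000,
    rng_seed: int | None = 0,
) -> VpcSummary:
    """Visual predictive check of ``data`` against the model.

    Simulates ``n_sim`` replicates of the design, dose-normalizes all
    concentrations to a 4 mg midazolam dose, and compares observed
    2.5/50/97.5 percentiles per nominal-time bin with their 90%
    simulation intervals.  Deterministic for a fixed seed.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100 for stable percentile bands")
    obs = _normalized_obs(data, _NORM_DOSE_MG)
    observed = _bin_percentiles(obs)
    seeds = np.random.SeedSequence(rng_seed).generate_state(n_sim)
    sim_pctls: dict[tuple, list[np.ndarray]] = {
        (r.TRT, r.CMT, r.time): [] for r in observed.itertuples()
    }
    bin_map = {
        (r.TRT, r.CMT, r.time): r.bin_times for r in observed.itertuples()
    }
    for s in seeds:
        rep = simulate_dataset(design, pop, re, effects_map, rng_seed=int(s))
        robs = _normalized_obs(rep, _NORM_DOSE_MG)
        for (trt, cmt, t), bin_times in bin_map.items():
            sel = robs[(robs["TRT"] == trt) & (robs["CMT"] == cmt)
                       & (robs["TIME"].isin(bin_times))]
            if len(sel):
                sim_pctls[(trt, cmt, t)].append(np.percentile(sel["DVN"], _PCTL))
    out = observed.rename(
        columns={"p2_5": "obs_p2_5", "p50": "obs_p50", "p97_5": "obs_p97_5"}
    ).drop(columns=["bin_times"])
    for which, j in (("p2_5", 0), ("p50", 1), ("p97_5", 2)):
        lo, hi = [], []
        for r in observed.itertuples():
            arr = np.array([p[j] for p in sim_pctls[(r.TRT, r.CMT, r.time)]])
            b = np.percentile(arr, _BAND)
            lo.append(b[0])
            hi.append(b[1])
        out[f"sim_{which}_lo"] = lo
        out[f"sim_{which}_hi"] = hi
    return VpcSummary(table=out, n_sim=n_sim)


def compute_residuals(
    data: pd.DataFrame,
    pop: PopulationParameters,
    re: RandomEffectsSpec,
    effects_map: Mapping[str, TreatmentEffects] | None = None,
) -> pd.DataFrame:
    """Individual and population predictions with weighted residuals.

    ``IPRED`` uses each subject's MAP random effects, ``PRED`` the typical
    individual (all random effects zero).  ``IWRES = (DV - IPRED) /
    (sigma * IPRED)``; ``PWRES`` is the analogous population residual with
    an FO-style weight ``sigma * PRED`` (an approximation of conditional
    weighted residuals).  ``outlier`` flags |IWRES| > 1.96.  The function
    is deterministic: repeated calls give identical tables.
    """
    if effects_map is None:
        effects_map = {"constitutive": TreatmentEffects()}
    sdatas = prepare_dataset(data, pop, effects_map)
    rows = []
    from .estimation import _map_fit  # local to avoid cycle at import time

    def _predict(sl, sdata, z):
        preds = []
        mults = sl._multipliers(z[None, :])
        for occ, mult in zip(sdata.occasions, mults):
            p = sl._build_params(mult, 1)
            A = sl._rate_matrices(p, 1)
            c_mdz, c_oh = sl._propagate(A, occ, p["F"], p["Vc"], p["Vmet"])
            preds.append(np.where(occ.analyte_idx == 0,
                                  c_mdz[0, occ.time_idx], c_oh[0, occ.time_idx]))
        return preds

    for sdata in sdatas:
        eff = effects_map[sdata.category]
        sl = _SubjectLikelihood(sdata, pop, re, eff)
        res = _map_fit(sl)
        ipreds = _predict(sl, sdata, res.z)
        ppreds = _predict(sl, sdata, np.zeros(sl.dim))
        for occ_i, (occ, ipred, ppred) in enumerate(
            zip(sdata.occasions, ipreds, ppreds), start=1
        ):
            iwres = (occ.dv - ipred) / (occ.sigma * np.maximum(ipred, 1e-12))
            pwres = (occ.dv - ppred) / (occ.sigma * np.maximum(ppred, 1e-12))
            for j in range(occ.dv.size):
                rows.append(
                    dict(ID=sdata.subject.id, OCC=occ_i, TRT=sdata.category,
                         CMT="MDZ" if occ.analyte_idx[j] == 0 else "OHMDZ",
                         TIME=float(occ.obs_times[occ.time_idx[j]]),
                         DV=float(occ.dv[j]), IPRED=float(ipred[j]),
                         PRED=float(ppred[j]), IWRES=float(iwres[j]),
                         PWRES=float(pwres[j]),
                         outlier=bool(abs(iwres[j]) > 1.96))
                )
    return pd.DataFrame(rows)


def plot_vpc(summary: VpcSummary, path=None):
    """Semi-log VPC panel per (arm, analyte); writes ``path`` if given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = summary.table
    panels = list(t.groupby(["TRT", "CMT"]))
    fig, axes = plt.subplots(
        len(panels), 1, figsize=(6, 3 * len(panels)), squeeze=False
    )
    for ax, ((trt, cmt), grp) in zip(axes[:, 0], panels):
        grp = grp.sort_values("time")
        ax.fill_between(grp["time"], grp["sim_p2_5_lo"], grp["sim_p2_5_hi"],
                        alpha=0.25, color="C0")
        ax.fill_between(grp["time"], grp["sim_p50_lo"], grp["sim_p50_hi"],
                        alpha=0.4, color="C0")
        ax.fill_between(grp["time"], grp["sim_p97_5_lo"], grp["sim_p97_5_hi"],
                        alpha=0.25, color="C0")
        ax.plot(grp["time"], grp["obs_p50"], "k-", lw=1.5)
        ax.plot(grp["time"], grp["obs_p2_5"], "k:", lw=1)
        ax.plot(grp["time"], grp["obs_p97_5"], "k:", lw=1)
        ax.set_yscale("log")
        ax.set_title(f"{trt} / {cmt}")
        ax.set_xlabel("time [h]")
        ax.set_ylabel(f"conc [nM], {summary.norm_dose_mg:g} mg-normalized")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
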