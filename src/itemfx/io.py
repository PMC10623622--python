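"""File I/O, run configuration, and the two-period pipeline driver.

The pipeline mirrors the full analysis workflow: for each measurement
period it fits the multi-state model without and with item-effect
variables, compares their fit, tabulates latent moments under every
requested reference item, and runs the outcome regressions with and
without the item-effect predictors.  Running it on two periods of the
same respondents is the cross-validation design: two independent
re-analyses, not a statistically coupled model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimation import fit
from .fit_indices import classify_fit, fit_report, lr_test
from .latent_moments import extract_latent_moments, reference_switch
from .model_spec import PanelDesign, build_spec
from .structural import StructuralSpec, compare_increment, fit_structural

__all__ = [
    "RunConfig",
    "read_panel_csv",
    "write_panel_csv",
    "missingness_report",
    "run_pipeline",
    "write_bundle",
]


@dataclass
class RunConfig:
    periods: dict[str, str]            # period label -> CSV path
    n_items: int = 5
    n_occasions: int = 3
    item_labels: tuple[str, ...] = ()
    references: tuple[int, ...] = (3, 5)
    estimator: str = "ml"
    chi2_scale: str = "N"
    outcomes: tuple[str, ...] = ()
    out_dir: str | None = None
    seed: int = 0
    bounds: tuple[float, float] | None = None

    @property
    def design(self) -> PanelDesign:
        return PanelDesign(
            n_items=self.n_items,
            n_occasions=self.n_occasions,
            item_labels=tuple(self.item_labels),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["periods"] = dict(raw["periods"])
        for key in ("references", "outcomes", "item_labels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if raw.get("bounds") is not None:
            raw["bounds"] = tuple(raw["bounds"])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_panel_csv(
    path: str | Path,
    design: PanelDesign,
    *,
    bounds: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Read a wide panel CSV (columns ``<item>_w<occasion>``; empty = missing).

    Raises descriptive errors on malformed headers, non-numeric cells,
    and (when ``bounds`` is given) out-of-range responses.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in design.observed_labels if c not in df.columns]
    if missing_cols:
        raise ValueError(
            f"{path}: header lacks expected panel columns {missing_cols}; "
            f"expected the <item>_w<occasion> convention"
        )
    for col in design.observed_labels:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: non-numeric cell in column "
                             f"{col!r}") from exc
    if bounds is not None:
        lo, hi = bounds
        vals = df.loc[:, list(design.observed_labels)]
        bad = (vals < lo) | (vals > hi)
        if bad.any().any():
            col = bad.any()[bad.any()].index[0]
            raise ValueError(
                f"{path}: response outside [{lo}, {hi}] in column {col!r}"
            )
    return df


def write_panel_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, na_rep="")


def missingness_report(df: pd.DataFrame, design: PanelDesign) -> pd.DataFrame:
    """Per-column missing counts plus the per-wave unit-nonresponse rate."""
    rows = []
    for occ in design.occasion_labels:
        cols = [f"{it}_w{occ}" for it in design.item_labels]
        wave_missing = df.loc[:, cols].isna().all(axis=1).sum()
        for c in cols:
            rows.append({"column": c, "n_missing": int(df[c].isna().sum()),
                         "wave": occ, "wave_unit_nonresponse": int(wave_missing)})
    return pd.DataFrame(rows)


def _indices_row(label: str, rep) -> dict:
    return {
        "model": label,
        "chi2": round(rep.chi2, 1),
        "df": rep.df,
        "rmsea": round(rep.rmsea, 3),
        "rmsea_ci90": [round(v, 3) for v in rep.rmsea_ci90],
        "srmr": round(rep.srmr, 3),
        "cfi": round(rep.cfi, 3),
        "tli": round(rep.tli, 3),
        "aic": round(rep.aic, 1),
        "bic": round(rep.bic, 1),
        "classification": classify_fit(rep),
    }


def _moment_entry(table) -> dict:
    entry = {
        "reference_item": table.reference_item,
        "labels": list(table.labels),
        "means": [round(v, 3) for v in table.means],
        "sds": [round(v, 3) for v in table.sds],
        "corr": np.round(table.corr, 3).tolist(),
    }
    if table.param_cov is not None:
        mean_f, sd_f, corr_f = table.flags()
        entry["nonsignificant_corr"] = [
            [table.labels[i], table.labels[j]]
            for i in range(len(table.labels)) for j in range(i)
            if not corr_f[i, j]
        ]
    return entry


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis on every configured period.

    Returns a JSON-serializable bundle; stage failures are captured in a
    ``failures`` manifest instead of aborting the whole run.
    """
    design = config.design
    bundle: dict = {
        "provenance": {
            "package": "itemfx",
            "version": __version__,
            "config_digest": config.digest(),
            "seed": config.seed,
            "estimator": config.estimator,
            "chi2_scale": config.chi2_scale,
        },
        "periods": {},
        "failures": [],
    }
    primary_ref = config.references[0]
    for period, source in config.periods.items():
        entry: dict = {}
        bundle["periods"][period] = entry
        try:
            data = (source if isinstance(source, pd.DataFrame)
                    else read_panel_csv(source, design, bounds=config.bounds))
        except Exception as exc:  # noqa: BLE001 - manifest, not crash
            bundle["failures"].append({"period": period, "stage": "read",
                                       "error": str(exc)})
            continue
        entry["missingness"] = {
            c: int(data[c].isna().sum()) for c in design.observed_labels
        }
        try:
            spec_states = build_spec("states_only", primary_ref, design)
            spec_fx = build_spec("item_effects", primary_ref, design)
            fit_states = fit(spec_states, data, estimator=config.estimator)
            fit_fx = fit(spec_fx, data, estimator=config.estimator)
            rep_states = fit_report(fit_states, scale=config.chi2_scale)
            rep_fx = fit_report(fit_fx, scale=config.chi2_scale)
            stat, ddf, pval = lr_test(fit_states, fit_fx)
            entry["fit_comparison"] = {
                "rows": [_indices_row("states_only", rep_states),
                         _indices_row("item_effects", rep_fx)],
                "lr_test": {"stat": round(stat, 1), "ddf": ddf,
                            "p": float(f"{pval:.3g}")},
                "preferred_by_aic": ("item_effects"
                                     if rep_fx.aic < rep_states.aic
                                     else "states_only"),
                "converged": {"states_only": fit_states.converged,
                              "item_effects": fit_fx.converged},
            }
        except Exception as exc:  # noqa: BLE001
            bundle["failures"].append({"period": period,
                                       "stage": "measurement",
                                       "error": str(exc)})
            continue
        try:
            table = extract_latent_moments(fit_fx)
            entry["latent_moments"] = {}
            for ref in config.references:
                t = (table if ref == table.reference_item
                     else reference_switch(table, ref))
                entry["latent_moments"][str(ref)] = _moment_entry(t)
        except Exception as exc:  # noqa: BLE001
            bundle["failures"].append({"period": period, "stage": "moments",
                                       "error": str(exc)})
        for outcome in config.outcomes:
            for ref in config.references:
                try:
                    base = build_spec("item_effects", ref, design)
                    red = fit_structural(
                        StructuralSpec(base, outcome, "states_only"),
                        data, estimator=config.estimator)
                    full = fit_structural(
                        StructuralSpec(base, outcome,
                                       "states_plus_item_effects"),
                        data, estimator=config.estimator)
                    inc = compare_increment(red, full)
                    entry.setdefault("structural", {}).setdefault(
                        outcome, {})[str(ref)] = {
                        "betas_reduced": {k: round(v, 3) for k, v in
                                          red.betas_std.items()},
                        "betas_full": {k: round(v, 3) for k, v in
                                       full.betas_std.items()},
                        "r2_reduced": round(red.r2, 3),
                        "r2_full": round(full.r2, 3),
                        "delta_r2": round(inc.delta_r2, 3),
                        "lr": {"stat": round(inc.lr_stat, 1),
                               "ddf": inc.ddf,
                               "p": float(f"{inc.p_value:.3g}")},
                        "collinearity_flag": full.collinearity_flag,
                        "converged": bool(red.converged and full.converged),
                    }
                except Exception as exc:  # noqa: BLE001
                    bundle["failures"].append(
                        {"period": period, "stage": f"structural:{outcome}",
                         "reference": ref, "error": str(exc)})
    if config.out_dir:
        write_bundle(bundle, config.out_dir)
    return bundle


def _json_scalar(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def _fit_comparison_tsv(bundle: dict) -> str:
    lines = ["period\tmodel\tchi2\tdf\trmsea\trmsea_ci90\tsrmr\tcfi\ttli"
             "\taic\tbic\tclass"]
    for period, entry in bundle["periods"].items():
        for row in entry.get("fit_comparison", {}).get("rows", []):
            ci = row["rmsea_ci90"]
            lines.append(
                f"{period}\t{row['model']}\t{row['chi2']}\t{row['df']}\t"
                f"{row['rmsea']:.3f}\t[{ci[0]:.3f}, {ci[1]:.3f}]\t"
                f"{row['srmr']:.3f}\t{row['cfi']:.3f}\t{row['tli']:.3f}\t"
                f"{row['aic']}\t{row['bic']}\t{row['classification']}"
            )
    return "\n".join(lines) + "\n"


def write_bundle(bundle: dict, out_dir: str | Path) -> None:
    """Write the bundle as JSON plus a fit-comparison TSV, with a
    provenance header on every file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = bundle["provenance"]
    header = (f"# itemfx {prov['version']} | config {prov['config_digest']} "
              f"| seed {prov['seed']}\n")
    with open(out / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True, default=_json_scalar)
        fh.write("\n")
    with open(out / "fit_comparison.tsv", "w") as fh:
        fh.write(header)
        fh.write(_fit_comparison_tsv(bundle))
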