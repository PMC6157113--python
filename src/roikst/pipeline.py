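"""End-to-end scans: kernel tests per region x window, interaction table.

These functions take aligned in-memory objects and return tidy result
DataFrames; the CLI wraps them with file I/O.  Per-region failures are
isolated: a failing region yields an NA row with the reason logged, and
never aborts the scan or perturbs other regions.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core_data import (MarkerAnnotation, MarkerMatrix, SampleTable)
from .exceptions import RoikstError
from .interaction_model import (fit_interaction_model,
                                fit_single_marker_regression,
                                pair_snp_with_nearest_cpg)
from .kernel_score_test import fit_null_model, kst_region_test
from .roi_builder import build_window_region
from .validation import (interaction_recovery_study, mixture_tail_study,
                         permutation_agreement_study, power_study,
                         single_marker_concordance_study, type1_error_study)

logger = logging.getLogger(__name__)

DEFAULT_WINDOWS_KBP = (15.0, 3.0, 0.0)


def run_kst_scan(table: SampleTable, markers: MarkerMatrix,
                 annotation: MarkerAnnotation,
                 anchors: Sequence[tuple[str, str]],
                 windows_kbp: Sequence[float] = DEFAULT_WINDOWS_KBP,
                 centering: bool = True, reml: bool = False,
                 adjust_bh: bool = False) -> pd.DataFrame:
    """Kernel score test per (anchor region x window) plus regressions.

    ``anchors`` is a sequence of (region_name, anchor_marker_id).  For
    each anchor, one row per window size carries the kernel-test p-value
    over all universe markers within the window, and one additional row
    carries the anchor's single-marker regression p-value — the
    region-scan layout of the analysis this package automates.
    """
    null = fit_null_model(table, reml=reml)
    universe = list(markers.marker_ids)
    rows = []
    for region_name, anchor in anchors:
        for w in windows_kbp:
            row = {"region": region_name, "anchor": anchor,
                   "analysis": "kst", "window_kbp": w, "n": table.n}
            try:
                region = build_window_region(
                    f"{region_name}@{w}", anchor, w, annotation, universe)
                members = [m for m in region.members if m in universe]
                Z = markers.restrict_markers(members)
                res = kst_region_test(table, Z, centering=centering,
                                      region_name=region_name, null=null)
                row.update(m=res.m, Q=res.Q, k=res.k, p_value=res.p_value,
                           method=res.method_used)
            except RoikstError as exc:
                logger.warning("region %s window %.1f failed: %s",
                               region_name, w, exc)
                row.update(m=np.nan, Q=np.nan, k=np.nan, p_value=np.nan,
                           method="NA")
            rows.append(row)
        row = {"region": region_name, "anchor": anchor,
               "analysis": "regression", "window_kbp": np.nan,
               "n": table.n}
        try:
            fit = fit_single_marker_regression(
                table, markers.restrict_markers([anchor]),
                region=region_name)
            row.update(m=1, Q=np.nan, k=np.nan,
                       p_value=fit.p("marker"), method="t_test")
        except RoikstError as exc:
            logger.warning("regression for %s failed: %s", region_name, exc)
            row.update(m=np.nan, Q=np.nan, k=np.nan, p_value=np.nan,
                       method="NA")
        rows.append(row)
    out = pd.DataFrame(rows)
    if adjust_bh:
        out["p_bh"] = _benjamini_hochberg(out["p_value"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests
    adj = np.full_like(p, np.nan, dtype=float)
    mask = np.isfinite(p)
    if mask.any():
        adj[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return adj


def run_interaction_scan(table: SampleTable, genotypes: MarkerMatrix,
                         methylation: MarkerMatrix,
                         annotation: MarkerAnnotation,
                         snp_ids: Sequence[str],
                         region_names: Sequence[str] | None = None,
                         center_inputs: bool = False) -> pd.DataFrame:
    """SNP x nearest-CpG interaction regression, one row per SNP."""
    cpg_universe = list(methylation.marker_ids)
    region_names = region_names or list(snp_ids)
    rows = []
    for region_name, snp_id in zip(region_names, snp_ids):
        row = {"region": region_name, "snp_id": snp_id, "n": table.n}
        try:
            cpg_id = pair_snp_with_nearest_cpg(snp_id, annotation,
                                               cpg_universe)
            fit = fit_interaction_model(
                table,
                genotypes.restrict_markers([snp_id]),
                methylation.restrict_markers([cpg_id]),
                center_inputs=center_inputs, region=region_name)
            row.update(cpg_id=cpg_id)
            for term, label in (("cpg", "cpg"), ("snp", "snp"),
                                ("snp_x_cpg", "interaction")):
                t = fit.terms[term]
                row[f"{label}_estimate"] = t.estimate
                row[f"{label}_se"] = t.stderr
                row[f"{label}_p"] = t.p_value
        except RoikstError as exc:
            logger.warning("interaction scan for %s failed: %s", snp_id, exc)
            row.setdefault("cpg_id", "NA")
            for label in ("cpg", "snp", "interaction"):
                row[f"{label}_estimate"] = np.nan
                row[f"{label}_se"] = np.nan
                row[f"{label}_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_validation_suite(seed: int, scale: float = 1.0) -> dict:
    """Run every validation study with seeds derived from one master seed.

    ``scale`` multiplies the replicate counts (use < 1 for a quick look;
    tolerances are statistical, so reduced runs are noisier).  Returns a
    nested dict of study results, including every derived seed.
    """
    rng = np.random.default_rng(seed)
    seeds = {name: int(rng.integers(2 ** 31)) for name in
             ("mixture", "permutation", "type1", "concordance",
              "recovery", "power")}
    s = lambda count: max(10, int(round(count * scale)))
    report = {
        "master_seed": seed,
        "seeds": seeds,
        "mixture_tail": mixture_tail_study(
            seeds["mixture"], n_spectra=max(5, int(25 * scale)),
            n_draws=s(10 ** 6)),
        "permutation_agreement": permutation_agreement_study(
            seeds["permutation"], n_datasets=max(6, int(20 * scale)),
            n_perm=max(1000, s(10 ** 4))),
        "type1": type1_error_study(seeds["type1"], n_reps=s(5000)),
        "concordance": single_marker_concordance_study(
            seeds["concordance"], n_datasets=s(200)),
        "recovery": interaction_recovery_study(seeds["recovery"]),
        "power": power_study(seeds["power"], n_reps=s(1000)),
    }
    report["all_pass"] = bool(
        report["mixture_tail"]["all_within_3se"]
        and report["mixture_tail"]["chi2_tail_abs_error"] <= 1e-4
        and report["permutation_agreement"]["all_within_3se"]
        and report["type1"]["rate_in_band"]
        and report["type1"]["uniform_at_1pct"]
        and report["concordance"]["spearman_rho"] > 0.99
        and report["recovery"]["recovered_within_3se"]
        and report["power"]["interaction_beats_snp_only_top"]
        and report["power"]["power_nonincreasing"]
    )
    return report


def write_results(df: pd.DataFrame, path: str | Path,
                  config_echo: dict | None = None,
                  seed: int | None = None) -> None:
    """Write a results TSV with '#'-prefixed provenance header lines."""
    path = Path(path)
    lines = [f"# roikst {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config_echo:
        blob = ";".join(f"{k}={v}" for k, v in sorted(config_echo.items()))
        digest = hashlib.sha1(blob.encode()).hexdigest()[:12]
        lines.append(f"# config: {blob}")
        lines.append(f"# config_sha1: {digest}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")
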