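"""Group statistics and the end-to-end analysis pipeline.

Statistical conventions follow common practice in mouse reproductive
phenotyping: two groups are compared with an unpaired two-tailed Student's
t-test (pooled variance; Welch optional); three or more groups with a
one-way ANOVA, followed by comparisons of each knockout group against the
wild-type control. Comparison p-values are coded as significance letters:

    a: p < 0.05      b: p < 0.01      c: p < 0.001

(the most extreme applicable letter; empty string otherwise).

The control-anchored comparisons default to Dunnett's procedure, the
standard many-to-one multiple-comparison method; Holm-adjusted pairwise
t-tests are available as an alternative. Degenerate inputs use documented
conventions instead of raising: zero within-group variance with equal
means reports p = 1; with unequal means, p = 0 (F = inf).

:func:`run_pipeline` orchestrates the whole analysis — synthetic
population (or contour CSV + manifest) -> EFD -> PCA -> scores, mean
shapes, optional stain measurements and kinematics -> group-comparison
tables — writing deterministic TSV/JSON outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._exceptions import ParameterError, ValidationError
from . import casa as casa_mod
from . import contour_io, efd, shape_pca, sperm_metrics, synth_shapes

__all__ = [
    "GroupComparison",
    "significance_letter",
    "one_way_anova",
    "t_test",
    "compare_to_control",
    "run_pipeline",
]


def significance_letter(p: float) -> str:
    """Map a p-value to the a/b/c significance code."""
    if p < 0.001:
        return "c"
    if p < 0.01:
        return "b"
    if p < 0.05:
        return "a"
    return ""


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA plus per-group comparisons against the control.

    ``table`` has one row per group: n, mean, sd, p_vs_control (NaN for
    the control itself) and the significance letter.
    """

    variable: str
    control: str
    F: float
    p: float
    table: pd.DataFrame
    method: str


def _validate_groups(groups) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2:
        raise ParameterError("need at least 2 groups")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ParameterError(f"group {i} has n < 2")
    return arrays


def one_way_anova(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F and p across >= 2 groups.

    Between/within mean squares on (k - 1, N - k) degrees of freedom.
    Degenerate convention: all within-group variance zero -> p = 1 if the
    group means are equal, else F = inf, p = 0.
    """
    arrays = _validate_groups(groups)
    means = [g.mean() for g in arrays]
    ssw = sum(((g - m) ** 2).sum() for g, m in zip(arrays, means))
    if ssw == 0.0:
        if np.ptp(means) == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F, p = sps.f_oneway(*arrays)
    return float(F), float(p)


def t_test(sample_a, sample_b, welch: bool = False) -> tuple[float, float]:
    """Unpaired two-tailed t-test; Student (pooled) by default.

    Degenerate convention: both samples constant -> t = 0, p = 1 when the
    means are equal; t = inf, p = 0 otherwise.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ParameterError("each sample needs n >= 2")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf"), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def compare_to_control(
    groups: dict,
    control_label: str,
    method: str = "dunnett",
    variable: str = "",
) -> GroupComparison:
    """Compare every group against the control and assign letters.

    ``groups`` maps label -> numeric sample. ``method='dunnett'`` uses
    Dunnett's many-to-one procedure; ``method='holm_t'`` Holm-adjusts
    pairwise Student t-tests against the control.
    """
    if control_label not in groups:
        raise ParameterError(f"control label {control_label!r} not among groups")
    labels = list(groups)
    arrays = {k: np.asarray(v, dtype=float).ravel() for k, v in groups.items()}
    _validate_groups(arrays.values())
    others = [k for k in labels if k != control_label]

    F, p_omni = one_way_anova(list(arrays.values()))

    if not others:
        pvals: dict[str, float] = {}
    elif method == "dunnett":
        degenerate = all(a.var(ddof=1) == 0.0 for a in arrays.values())
        if degenerate:
            pvals = {
                k: 1.0 if arrays[k].mean() == arrays[control_label].mean() else 0.0
                for k in others
            }
        else:
            # fixed internal rng: Dunnett's p is evaluated by stochastic
            # multivariate-t integration, and reports must be reproducible
            res = sps.dunnett(
                *[arrays[k] for k in others],
                control=arrays[control_label],
                rng=np.random.default_rng(0),
            )
            pvals = dict(zip(others, np.asarray(res.pvalue, dtype=float)))
    elif method == "holm_t":
        raw = [t_test(arrays[k], arrays[control_label])[1] for k in others]
        adj = multipletests(raw, method="holm")[1] if raw else []
        pvals = dict(zip(others, adj))
    else:
        raise ParameterError(f"unknown method {method!r}; use 'dunnett' or 'holm_t'")

    rows = []
    for k in labels:
        g = arrays[k]
        pv = pvals.get(k, np.nan)
        rows.append(
            {
                "group": k,
                "n": g.size,
                "mean": g.mean(),
                "sd": g.std(ddof=1),
                "p_vs_control": pv,
                "letter": "" if k == control_label else significance_letter(pv),
            }
        )
    return GroupComparison(
        variable=variable,
        control=control_label,
        F=F,
        p=p_omni,
        table=pd.DataFrame(rows),
        method=method,
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

_TSV = dict(sep="\t", index=False, float_format="%.12g")


def _coefficient_table(records, H: int, canonical_chirality: bool = False):
    """EFD-normalize every contour; returns (ids, groups, matrix)."""
    ids, groups, rows = [], [], []
    for sid, group, contour in records:
        coeffs = efd.normalize(
            efd.decompose(contour, H=H), canonical_chirality=canonical_chirality
        )
        ids.append(sid)
        groups.append(group)
        rows.append(efd.flatten(coeffs))
    return ids, groups, np.vstack(rows)


def _flat_matrix_frame(ids, groups, matrix, H):
    cols = [f"{c}{n}" for n in range(1, H + 1) for c in "abcd"]
    df = pd.DataFrame(matrix, columns=cols)
    df.insert(0, "group", groups)
    df.insert(0, "specimen_id", ids)
    return df


def _comparison_frame(comp: GroupComparison) -> pd.DataFrame:
    df = comp.table.copy()
    df.insert(0, "variable", comp.variable)
    df["omnibus_F"] = comp.F
    df["omnibus_p"] = comp.p
    df["method"] = comp.method
    return df


def run_pipeline(config: dict, outdir=None) -> dict:
    """Run the full morphometry analysis from a config dict.

    Simulation mode (``mode='simulate'``) generates the populations with
    :mod:`synth_shapes`; contour mode (``mode='contours'``) reads a contour
    CSV plus a TSV manifest (``specimen_id<TAB>group``). The analysis is:
    EFD (H harmonics) -> normalization -> PCA (n_components) -> per-PC
    group comparisons vs the control group; optionally rendered-stain
    measurements (acrosome area, vacuole prevalence) and track kinematics
    in simulation mode. Deterministic given config + seed.

    Returns the report bundle as a dict; when ``outdir`` is given, also
    writes coefficients/scores/measurements/comparison TSVs, mean-shape
    contour CSVs and a JSON + plain-text summary.
    """
    mode = config.get("mode", "simulate")
    H = int(config.get("harmonics", 20))
    n_components = int(config.get("n_components", 2))
    seed = int(config.get("seed", 0))
    control = config.get("control")

    bundle: dict = {"config": config, "tables": {}}

    # ---- collect (specimen, group, contour) records -------------------
    ground_truth: dict[str, synth_shapes.HeadParams] = {}
    if mode == "simulate":
        records = []
        rng = np.random.default_rng(seed)
        group_specs = []
        for gconf in config["groups"]:
            mean = synth_shapes.HeadParams(**gconf.get("head_params", {}))
            spec = synth_shapes.PopulationSpec(
                label=gconf["label"],
                n=int(gconf["n"]),
                mean=mean,
                sd=gconf.get("head_params_sd", {}),
                n_points=int(config.get("n_points", 256)),
                seed=int(rng.integers(2**31)),
            )
            group_specs.append((gconf, spec))
            for sid, contour, params in synth_shapes.make_population(spec):
                records.append((sid, spec.label, contour))
                ground_truth[sid] = params
        if control is None:
            control = config["groups"][0]["label"]
    elif mode == "contours":
        contours = contour_io.read_contours(config["contours"])
        manifest = pd.read_csv(config["manifest"], sep="\t")
        if not {"specimen_id", "group"} <= set(manifest.columns):
            raise ValidationError("manifest must have columns specimen_id and group")
        group_of = dict(zip(manifest["specimen_id"].astype(str), manifest["group"]))
        unmatched = [sid for sid, _ in contours if str(sid) not in group_of]
        if unmatched:
            raise ValidationError(
                "specimens missing from manifest: " + ", ".join(map(str, unmatched))
            )
        records = [(str(sid), group_of[str(sid)], c) for sid, c in contours]
        if control is None:
            control = manifest["group"].iloc[0]
    else:
        raise ParameterError(f"unknown mode {config['mode']!r}")

    if len(records) < 2:
        raise ParameterError("need at least 2 specimens")

    # ---- EFD + PCA -----------------------------------------------------
    ids, groups, matrix = _coefficient_table(
        records, H, bool(config.get("canonical_chirality", False))
    )
    model = shape_pca.fit_pca(matrix, n_components=n_components)
    scores = shape_pca.score_table(model, matrix, ids, groups)
    bundle["model"] = model
    bundle["tables"]["coefficients"] = _flat_matrix_frame(ids, groups, matrix, H)
    bundle["tables"]["scores"] = scores

    # ---- mean shapes at 0 / ±2 SD per PC -------------------------------
    sd_multiples = config.get("mean_shape_sd_multiples", [-2.0, 0.0, 2.0])
    mean_shapes = []
    for k in range(1, n_components + 1):
        for m in sd_multiples:
            mean_shapes.append(
                (f"PC{k}_sd{m:+g}", shape_pca.mean_shape(model, k, m))
            )
    bundle["mean_shapes"] = mean_shapes

    # ---- group comparisons on PC scores -------------------------------
    comparisons: list[GroupComparison] = []
    by_group = {g: scores.loc[scores["group"] == g] for g in dict.fromkeys(groups)}
    if len(by_group) >= 2 and all(len(v) >= 2 for v in by_group.values()):
        for k in range(1, n_components + 1):
            comparisons.append(
                compare_to_control(
                    {g: df[f"PC{k}"].to_numpy() for g, df in by_group.items()},
                    control_label=control,
                    method=config.get("comparison_method", "dunnett"),
                    variable=f"PC{k}",
                )
            )

    # ---- optional rendered-stain measurements (simulation mode) -------
    measurements = None
    if mode == "simulate" and config.get("render"):
        rspec = synth_shapes.RenderSpec(**config["render"])
        rng_render = np.random.default_rng(seed + 1)
        center = np.array([rspec.image_shape[1] / 2.0, rspec.image_shape[0] / 2.0])
        rows = []
        vac_by_group: dict[str, list] = {}
        for sid, group, contour in records:
            shifted = contour_io.Contour(contour.points + center)
            rendered = synth_shapes.render_head_image(
                shifted, rspec, seed=int(rng_render.integers(2**31))
            )
            acro = sperm_metrics.acrosome_area(
                rendered.channels["acrosome"], rendered.head_mask,
                pixel_size=rspec.pixel_size, specimen_id=sid,
            )
            vac = sperm_metrics.detect_vacuoles(
                rendered.channels["nuclear"], rendered.head_mask, specimen_id=sid
            )
            vac_by_group.setdefault(group, []).append(vac)
            rows.append(
                {
                    "specimen_id": sid,
                    "group": group,
                    "acrosome_area_um2": acro.area_um2,
                    "head_area_um2": acro.head_area_um2,
                    "vacuole_count": vac.count,
                }
            )
        measurements = pd.DataFrame(rows)
        bundle["tables"]["measurements"] = measurements
        if len(by_group) >= 2 and all(len(v) >= 2 for v in by_group.values()):
            comparisons.append(
                compare_to_control(
                    {
                        g: measurements.loc[measurements["group"] == g, "acrosome_area_um2"].to_numpy()
                        for g in by_group
                    },
                    control_label=control,
                    method=config.get("comparison_method", "dunnett"),
                    variable="acrosome_area_um2",
                )
            )
        bundle["vacuole_prevalence"] = {
            g: sperm_metrics.prevalence(v) for g, v in vac_by_group.items()
        }

    # ---- optional kinematics (simulation mode) -------------------------
    if mode == "simulate" and config.get("tracks"):
        tconf = config["tracks"]
        rng_tracks = np.random.default_rng(seed + 2)
        kin_rows = []
        for gconf, _ in group_specs:
            label = gconf["label"]
            gt = tconf.get(label, tconf.get("default", {}))
            n_tracks = int(gt.get("n", 30))
            for j in range(n_tracks):
                speed = float(
                    rng_tracks.normal(gt.get("speed", 100.0), gt.get("speed_sd", 0.0))
                )
                track = synth_shapes.make_track(
                    model=gt.get("model", "sinusoid"),
                    speed=max(speed, 0.0),
                    duration=float(gt.get("duration", 1.0)),
                    frame_rate=float(gt.get("frame_rate", 60.0)),
                    amplitude=float(gt.get("amplitude", 4.0)),
                    frequency=float(gt.get("frequency", 8.0)),
                    seed=int(rng_tracks.integers(2**31)),
                    track_id=f"{label}_t{j:03d}",
                )
                s = casa_mod.summarize_track(track)
                kin_rows.append(
                    {
                        "track_id": s.track_id,
                        "group": label,
                        "VSL": s.VSL,
                        "VCL": s.VCL,
                        "VAP": s.VAP,
                        "motile": s.motile,
                    }
                )
        kinematics = pd.DataFrame(kin_rows)
        bundle["tables"]["kinematics"] = kinematics
        for var in ("VSL", "VCL", "VAP"):
            grouped = {
                g: kinematics.loc[kinematics["group"] == g, var].to_numpy()
                for g in kinematics["group"].unique()
            }
            if len(grouped) >= 2 and all(v.size >= 2 for v in grouped.values()):
                comparisons.append(
                    compare_to_control(
                        grouped,
                        control_label=control,
                        method=config.get("comparison_method", "dunnett"),
                        variable=var,
                    )
                )

    bundle["comparisons"] = comparisons
    if comparisons:
        bundle["tables"]["comparisons"] = pd.concat(
            [_comparison_frame(c) for c in comparisons], ignore_index=True
        )

    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in bundle["tables"].items():
        df.to_csv(outdir / f"{name}.tsv", **_TSV)
    contour_io.write_contours(outdir / "mean_shapes.csv", bundle["mean_shapes"])
    if "model" in bundle:
        bundle["model"].to_json(outdir / "pca_model.json")

    summary: dict = {
        "n_specimens": int(len(bundle["tables"]["coefficients"])),
        "explained_variance_ratio": bundle["model"].explained_variance_ratio.tolist(),
        "comparisons": [
            {
                "variable": c.variable,
                "control": c.control,
                "omnibus_F": c.F,
                "omnibus_p": c.p,
                "method": c.method,
                "groups": c.table.to_dict(orient="records"),
            }
            for c in bundle.get("comparisons", [])
        ],
    }
    if "vacuole_prevalence" in bundle:
        summary["vacuole_prevalence"] = {
            g: {"fraction": frac, "wilson_95ci": list(ci)}
            for g, (frac, ci) in bundle["vacuole_prevalence"].items()
        }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    lines = [
        f"specimens: {summary['n_specimens']}",
        "explained variance ratio: "
        + ", ".join(f"{v:.4f}" for v in summary["explained_variance_ratio"]),
    ]
    for c in summary["comparisons"]:
        lines.append(
            f"{c['variable']}: F={c['omnibus_F']:.4g} p={c['omnibus_p']:.4g} "
            f"({c['method']}, control={c['control']})"
        )
        for g in c["groups"]:
            if g["group"] == c["control"]:
                lines.append(
                    f"  {g['group']}: n={g['n']} mean={g['mean']:.4g} sd={g['sd']:.4g} (control)"
                )
            else:
                letter = g["letter"] or "ns"
                lines.append(
                    f"  {g['group']}: n={g['n']} mean={g['mean']:.4g} sd={g['sd']:.4g} "
                    f"p={g['p_vs_control']:.4g} [{letter}]"
                )
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
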