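"""End-to-end analysis: from torsion series (and optional geometry and
secondary structure) to the tabular report bundle.

The bundle reproduces the study's summary artifacts on any input:
per-pair correlation records; MI and MPMI matrices; the MI-vs-r scatter
with pair-type and distance strata; the linear/nonlinear x DSP/SMP/DMP
contingency table; per-torsion convergence fractions; permutation-null
maxima; and optional trajectory-subset results. Everything is
deterministic given the configuration and seed.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import correlation as corr
from . import diagnostics as diag
from .correlation import ContourModel, CorrelationRecord, DEFAULT_CONTOUR
from .distributions import DEFAULT_BINS
from .geometry import (
    SecondaryStructureAssignment,
    StructureFrame,
    TorsionIndexMap,
    TorsionSeries,
    inter_torsion_distance,
    map_secondary_structure,
    pair_type,
    read_dssp_codes,
    read_pdb_frames,
    read_torsion_table,
    build_torsion_index,
    extract_torsion_series,
)

__all__ = ["AnalysisConfig", "run_pipeline", "analyze_series", "stratify_pairs"]

LOCAL_CUTOFF = 8.0  # Angstrom; <= cutoff is spatially local, else long-range


@dataclass
class AnalysisConfig:
    """Every knob of the pipeline, with the study's defaults."""

    torsion_table: str | None = None
    pdb_path: str | None = None
    dssp_paths: list[str] = field(default_factory=list)
    reference_pdb: str | None = None  # distances; defaults to pdb_path
    output_dir: str = "btpcorr_out"
    n_bins: int = DEFAULT_BINS
    contour: str = "default_calibrated"  # or "refit"
    nonlinear_threshold: float = 0.02
    local_cutoff: float = LOCAL_CUTOFF
    thin_stride: int | None = None
    thin_uniform_count: int | None = None
    n_subsets: int = 20
    run_subsets: bool = False
    convergence_splits: int = 3
    convergence_threshold: float = 0.2
    permutation_rounds: int = 10
    permutation_pairs: int = 5  # top-MI pairs to run the null on
    exclude_adjacent: bool = False
    drop_unstable: bool = False
    seed: int = 0

    def validate(self) -> None:
        for v in (self.nonlinear_threshold, self.local_cutoff,
                  self.convergence_threshold):
            if v <= 0:
                raise ValueError("thresholds and cutoffs must be positive")
        for p in filter(None, [self.torsion_table, self.pdb_path,
                               self.reference_pdb, *self.dssp_paths]):
            if not os.path.exists(p):
                raise FileNotFoundError(p)


def analyze_series(
    series: list[TorsionSeries],
    model: ContourModel | None = None,
    distances: dict[tuple[int, int], float] | None = None,
    ss: SecondaryStructureAssignment | None = None,
    n_bins: int = DEFAULT_BINS,
    threshold: float = 0.02,
    exclude_adjacent: bool = False,
    drop_unstable: bool = False,
) -> list[CorrelationRecord]:
    """Correlation records for all unordered torsion pairs (i < j).

    Sequence-adjacent pairs (|index difference| = 1) can be excluded
    from the universe; unstable-r records are retained and flagged
    unless ``drop_unstable``.
    """
    model = model or DEFAULT_CONTOUR
    by_index = {s.index: s for s in series}
    records = []
    for i, j in itertools.combinations(sorted(by_index), 2):
        if exclude_adjacent and abs(i - j) == 1:
            continue
        x, y = by_index[i], by_index[j]
        pt = None
        if ss is not None:
            try:
                pt = pair_type(ss[x.residue_number], ss[y.residue_number])
            except KeyError:
                pt = None
        elif x.ss_class and y.ss_class:
            pt = pair_type(x.ss_class, y.ss_class)
        rec = corr.correlate_pair(
            x, y, model=model, n_bins=n_bins, threshold=threshold,
            distance=None if distances is None else distances.get((i, j)),
            pair_type=pt,
        )
        if drop_unstable and rec.instability_flag:
            continue
        records.append(rec)
    return records


def stratify_pairs(
    records: list[CorrelationRecord], cutoff: float = LOCAL_CUTOFF
) -> pd.DataFrame:
    """Counts and nonlinear fractions in the 2x3 distance x pair-type strata.

    A pair is spatially local when its inter-torsion distance is
    <= cutoff (boundary inclusive), long-range otherwise. Records
    without a distance or pair type are skipped with a warning.
    """
    import warnings

    rows = []
    skipped = 0
    for rec in records:
        if rec.distance is None or rec.pair_type is None:
            skipped += 1
            continue
        rows.append({
            "range": "local" if rec.distance <= cutoff else "long_range",
            "pair_type": rec.pair_type,
            "nonlinear": rec.linearity_class == "nonlinear",
        })
    if skipped:
        warnings.warn(f"{skipped} records lacked distance or pair type; "
                      "skipped from stratification", stacklevel=2)
    if not rows:
        return pd.DataFrame(columns=["range", "pair_type", "n", "n_nonlinear",
                                     "fraction_nonlinear"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["range", "pair_type"])
        .agg(n=("nonlinear", "size"), n_nonlinear=("nonlinear", "sum"))
        .reset_index()
    )
    out["fraction_nonlinear"] = out["n_nonlinear"] / out["n"]
    return out


def contingency_table(records: list[CorrelationRecord]) -> pd.DataFrame:
    """Linear/nonlinear x DSP/SMP/DMP counts and percentages."""
    rows = []
    total = len(records)
    for lin in ("linear", "nonlinear"):
        for trans in ("DSP", "SMP", "DMP"):
            n = sum(1 for r in records
                    if r.linearity_class == lin and r.transition_class == trans)
            rows.append({
                "linearity": lin, "transition": trans, "n": n,
                "percent": round(100.0 * n / total, 1) if total else 0.0,
            })
    return pd.DataFrame(rows)


def records_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    """Tidy per-pair table of every CorrelationRecord field."""
    return pd.DataFrame([
        {
            "i": r.pair[0], "j": r.pair[1], "M": r.M, "r": r.r,
            "S_x": r.S_x, "S_y": r.S_y, "S_xy": r.S_xy, "MI": r.MI,
            "MPMI_r": r.MPMI_r, "excess": r.excess,
            "linearity": r.linearity_class, "transition": r.transition_class,
            "pair_type": r.pair_type, "distance": r.distance,
            "unstable": r.instability_flag, "degenerate": r.degenerate_flag,
        }
        for r in records
    ])


def _matrix(records, n_torsions: int, attr: str) -> np.ndarray:
    m = np.full((n_torsions, n_torsions), np.nan)
    for r in records:
        i, j = r.pair
        v = getattr(r, attr)
        m[i - 1, j - 1] = m[j - 1, i - 1] = v if np.isfinite(v) else np.nan
    return m


def _load_inputs(config: AnalysisConfig):
    """Resolve series, distances and SS classes from the configured files."""
    distances = None
    ss = None
    imap: TorsionIndexMap | None = None
    if config.torsion_table:
        series = read_torsion_table(config.torsion_table)
        imap = build_torsion_index(len(series) // 2 + 1)
    elif config.pdb_path:
        frames = read_pdb_frames(config.pdb_path, models=None)
        all_frames = read_pdb_frames(
            config.pdb_path,
            models=list(range(_count_models(config.pdb_path))),
        )
        imap = build_torsion_index(len(frames[0].residue_numbers))
        series = extract_torsion_series(all_frames, imap)
    else:
        raise ValueError("config must name a torsion table or a PDB file")

    ref_path = config.reference_pdb or config.pdb_path
    if ref_path:
        ref = read_pdb_frames(ref_path)[0]
        if imap is not None and len(ref.residue_numbers) != imap.n_residues:
            raise ValueError(
                f"reference structure has {len(ref.residue_numbers)} residues, "
                f"torsion input implies {imap.n_residues}"
            )
        distances = {}
        for a, b in itertools.combinations(range(1, len(imap) + 1), 2):
            distances[(a, b)] = inter_torsion_distance(ref, imap, a, b)
    if config.dssp_paths:
        tables = [read_dssp_codes(p) for p in config.dssp_paths]
        ss = map_secondary_structure(tables)
    return series, distances, ss


def _count_models(path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                n += 1
    return max(n, 1)


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Writes records.tsv, mi_matrix.tsv, mpmi_matrix.tsv, scatter.tsv,
    contingency.tsv (linear/nonlinear x DSP/SMP/DMP), convergence.tsv,
    permutation.tsv, strata.tsv (when distances and SS are available),
    subsets.tsv (optional) and config.json into ``config.output_dir``.
    Returns the bundle as in-memory objects. Byte-identical across
    reruns with the same config and seed.
    """
    config.validate()
    os.makedirs(config.output_dir, exist_ok=True)
    series, distances, ss = _load_inputs(config)

    if config.thin_stride or config.thin_uniform_count:
        series = diag.thin_snapshots(
            series, stride=config.thin_stride,
            uniform_count=config.thin_uniform_count,
        )

    model = DEFAULT_CONTOUR
    records = analyze_series(
        series, model=model, distances=distances, ss=ss,
        n_bins=config.n_bins, threshold=config.nonlinear_threshold,
        exclude_adjacent=config.exclude_adjacent,
        drop_unstable=config.drop_unstable,
    )
    if config.contour == "refit":
        model = corr.fit_contour([(r.r, r.MI) for r in records])
        records = analyze_series(
            series, model=model, distances=distances, ss=ss,
            n_bins=config.n_bins, threshold=config.nonlinear_threshold,
            exclude_adjacent=config.exclude_adjacent,
            drop_unstable=config.drop_unstable,
        )

    out = config.output_dir
    rec_df = records_frame(records)
    rec_df.to_csv(os.path.join(out, "records.tsv"), sep="\t", index=False,
                  float_format="%.6g")

    n_t = max(max(r.pair) for r in records) if records else 0
    labels = [f"t{k}" for k in range(1, n_t + 1)]
    for fname, attr in (("mi_matrix.tsv", "MI"), ("mpmi_matrix.tsv", "MPMI_r")):
        pd.DataFrame(_matrix(records, n_t, attr), index=labels,
                     columns=labels).to_csv(
            os.path.join(out, fname), sep="\t", float_format="%.6g")

    scatter = rec_df[["i", "j", "r", "MI", "pair_type", "distance"]].copy()
    if distances is not None:
        scatter["range"] = np.where(
            scatter["distance"] <= config.local_cutoff, "local", "long_range")
    scatter.to_csv(os.path.join(out, "scatter.tsv"), sep="\t", index=False,
                   float_format="%.6g")

    cont = contingency_table(records)
    cont.to_csv(os.path.join(out, "contingency.tsv"), sep="\t", index=False)

    conv = diag.convergence_check(
        series, n_splits=config.convergence_splits,
        threshold=config.convergence_threshold, n_bins=config.n_bins,
    )
    conv_df = pd.DataFrame([
        {"torsion": t, "max_kl": max(v), "converged": conv.converged[t]}
        for t, v in sorted(conv.kl_values.items())
    ])
    conv_df.to_csv(os.path.join(out, "convergence.tsv"), sep="\t", index=False,
                   float_format="%.6g")

    by_index = {s.index: s for s in series}
    top = sorted(records, key=lambda r: -r.MI)[: config.permutation_pairs]
    perm_rows = []
    for k, r in enumerate(top):
        mr, mmi = diag.permutation_null(
            by_index[r.pair[0]], by_index[r.pair[1]],
            n_rounds=config.permutation_rounds,
            seed=config.seed + k, n_bins=config.n_bins,
        )
        perm_rows.append({"i": r.pair[0], "j": r.pair[1],
                          "max_abs_r": mr, "max_MI": mmi})
    perm_df = pd.DataFrame(perm_rows)
    perm_df.to_csv(os.path.join(out, "permutation.tsv"), sep="\t", index=False,
                   float_format="%.6g")

    strata = stratify_pairs(records, cutoff=config.local_cutoff) \
        if distances is not None else None
    if strata is not None:
        strata.to_csv(os.path.join(out, "strata.tsv"), sep="\t", index=False,
                      float_format="%.6g")

    subset_df = None
    if config.run_subsets and top:
        rows = []
        for r in top:
            sres = diag.subset_analysis(
                by_index[r.pair[0]], by_index[r.pair[1]],
                n_subsets=config.n_subsets, n_bins=config.n_bins,
            )
            for s in sres.subsets:
                rows.append({"i": r.pair[0], "j": r.pair[1], **s,
                             "full_MI": sres.full_MI, "full_r": sres.full_r})
        subset_df = pd.DataFrame(rows)
        subset_df.to_csv(os.path.join(out, "subsets.tsv"), sep="\t",
                         index=False, float_format="%.6g")

    with open(os.path.join(out, "config.json"), "w") as fh:
        json.dump({k: v for k, v in config.__dict__.items()}, fh,
                  indent=1, sort_keys=True)

    return {
        "records": records,
        "contingency": cont,
        "convergence": conv,
        "permutation": perm_df,
        "strata": strata,
        "subsets": subset_df,
        "contour": model,
    }
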