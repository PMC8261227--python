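"""End-to-end analysis: events in, structured report of hierarchy and
network statistics out.

The report mirrors how such studies present results: sampling
sufficiency; group-level dominance metrics (per event type and combined,
for the female subset and the whole colony) against direction-randomized
nulls; David's scores and steepness; individual ranks from three methods
with their agreement; rank-uncertainty diagnostics; the hierarchy-shape
curve; and, when cooperation matrices are supplied, the dyadic network
tests (conflict predictors, rank-directed helping, help symmetry,
feeding-time permutation test).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import events as ev_mod
from . import metrics as met
from . import network as net
from . import ratings as rat
from . import uncertainty as unc
from .events import EventTable, build_win_lose_matrix, read_events
from .network import DyadicMatrix


@dataclass
class AnalysisConfig:
    n_perm: int = 5000
    n_null_reps: int = 5000
    n_boot: int = 5000
    n_uncertainty_reps: int = 10
    elo_k: float = 100.0
    elo_start: float = 1000.0
    glicko_r0: float = 1500.0
    glicko_rd0: float = 350.0
    glicko_rd_floor: float = 30.0
    davids_correction: str = "raw"
    shape_bin_width: float = 1.0
    per_event_type: bool = True
    rosters: tuple = ("females", "all")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class AnalysisReport:
    sampling: dict
    group_metrics: dict  # roster -> event type/"combined" -> metric -> dict
    davids: pd.DataFrame
    steepness: dict
    ranks: pd.DataFrame  # per individual x method
    rank_agreement: dict  # "a_vs_b" -> {r, p}
    uncertainty: dict
    shape: pd.DataFrame
    network_tests: dict
    gaps: list
    metadata: dict

    def to_dict(self) -> dict:
        return {
            "sampling": self.sampling,
            "group_metrics": self.group_metrics,
            "davids": self.davids.to_dict(orient="list"),
            "steepness": self.steepness,
            "ranks": self.ranks.to_dict(orient="list"),
            "rank_agreement": self.rank_agreement,
            "uncertainty": self.uncertainty,
            "shape": self.shape.to_dict(orient="list"),
            "network_tests": self.network_tests,
            "gaps": self.gaps,
            "metadata": self.metadata,
        }


def _stage_seeds(master: int, names: list[str]) -> dict[str, int]:
    rng = np.random.default_rng(master)
    return {name: int(rng.integers(2**31)) for name in names}


def _roster_ids(table: EventTable, which: str) -> list[str]:
    if which == "all":
        return table.ids
    if which == "females":
        r = table.roster
        return list(r.loc[r["sex"] == "F", "id"])
    if which == "adult_females":
        r = table.roster
        return list(r.loc[(r["sex"] == "F") & (r["age_class"] == "adult"), "id"])
    raise ValueError(f"unknown roster {which!r}")


def conflict_matrix_from_events(
    table: EventTable, ids: list[str] | None = None
) -> DyadicMatrix:
    """Symmetric dyadic competitive-interaction counts."""
    m = build_win_lose_matrix(table, ids=ids)
    return DyadicMatrix(
        m.ids, (m.W + m.W.T).astype(float), "conflict", symmetric=True
    )


def run_full_analysis(
    events: EventTable | str | Path,
    roster_path=None,
    networks: dict[str, DyadicMatrix] | None = None,
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Run every analysis stage; missing optional inputs yield explicit gaps.

    ``networks`` may hold ``kinship``, ``grooming``, ``sharing`` (rates in
    seconds per trial; the ln(x+1) transform is applied internally) and
    optionally ``co_observation``.  Stage seeds are spawned from
    ``config.seed`` and recorded, so every stage is independently
    reproducible.
    """
    cfg = config or AnalysisConfig()
    if not isinstance(events, EventTable):
        if roster_path is None:
            raise ValueError("roster_path required when events is a file path")
        events = read_events(events, roster_path)
    table = events
    gaps: list[str] = []
    seeds = _stage_seeds(
        cfg.seed,
        ["sampling", "group", "steepness", "uncertainty", "network", "rank_time"],
    )

    combined = build_win_lose_matrix(table)
    sampling = ev_mod.sampling_summary(
        combined, table, null_reps=cfg.n_null_reps, seed=seeds["sampling"]
    ).to_dict()

    # group metrics per roster and event type
    group: dict = {}
    type_sets: list[tuple[str, tuple | None]] = [("combined", None)]
    if cfg.per_event_type:
        type_sets += [(t, (t,)) for t in ev_mod.EVENT_TYPES]
    for roster_name in cfg.rosters:
        ids = _roster_ids(table, roster_name)
        group[roster_name] = {}
        for label, types in type_sets:
            try:
                m = build_win_lose_matrix(table, types=types, ids=ids)
                res = met.group_metrics(m, n_perm=cfg.n_perm, seed=seeds["group"])
                group[roster_name][label] = {
                    k: v.to_dict() for k, v in res.items()
                }
            except (ValueError, met.UndefinedMetricError) as exc:
                gaps.append(f"group_metrics[{roster_name}][{label}]: {exc}")

    # David's scores, steepness (primary roster = females, falling back to all)
    primary = "females" if "females" in cfg.rosters else cfg.rosters[0]
    primary_ids = _roster_ids(table, primary)
    primary_m = build_win_lose_matrix(table, ids=primary_ids)
    ds = met.davids_scores(primary_m, correction=cfg.davids_correction)
    steep = met.steepness(
        primary_m, n_perm=cfg.n_perm, seed=seeds["steepness"],
        correction=cfg.davids_correction,
    )
    steepness = {"roster": primary, **steep.to_dict()}

    # three ranking methods on the full roster
    ds_all = met.davids_scores(combined, correction=cfg.davids_correction)
    davids_rr = rat.RankResult("davids", combined.ids, ds_all.DS)
    _, elo_rr = rat.elo_sequence(
        table, k=cfg.elo_k, start=cfg.elo_start, allow_unordered=True
    )
    _, glicko_rr = rat.glicko_sequence(
        table, r0=cfg.glicko_r0, rd0=cfg.glicko_rd0,
        rd_floor=cfg.glicko_rd_floor, allow_unordered=True,
    )
    ranks = pd.concat(
        [davids_rr.to_frame(), elo_rr.to_frame(), glicko_rr.to_frame()],
        ignore_index=True,
    )
    agreement = {}
    for (na, ra), (nb, rb) in (
        (("davids", davids_rr), ("elo", elo_rr)),
        (("davids", davids_rr), ("glicko", glicko_rr)),
        (("elo", elo_rr), ("glicko", glicko_rr)),
    ):
        r, p = rat.rank_agreement(ra, rb)
        agreement[f"{na}_vs_{nb}"] = {"r": r, "p": p}

    uncertainty = {}
    for name, fn in (
        ("repeatability", unc.uncertainty_by_repeatability),
        ("splitting", unc.uncertainty_by_splitting),
    ):
        uncertainty[name] = fn(
            table, n_reps=cfg.n_uncertainty_reps, k=cfg.elo_k,
            start=cfg.elo_start, seed=seeds["uncertainty"],
        ).to_dict()

    scores_all = davids_rr.score_of()
    shape = met.hierarchy_shape(
        table, scores_all, bin_width=cfg.shape_bin_width
    ).table

    # dyadic network tests on the adult-female roster
    network_tests: dict = {}
    network_tests["rank_time"] = net.rank_time_permutation_test(
        table, scores_all, n_perm=cfg.n_perm, seed=seeds["rank_time"]
    ).to_dict()
    if networks:
        network_tests.update(
            _network_stage(table, networks, scores_all, cfg, seeds["network"], gaps)
        )
    else:
        gaps.append("network_tests: no cooperation matrices supplied")

    metadata = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(cfg).items()},
        "stage_seeds": seeds,
        "n_individuals": len(table.ids),
        "n_events_usable": int(len(table.usable)),
    }
    return AnalysisReport(
        sampling, group, ds.to_frame(), steepness, ranks, agreement,
        uncertainty, shape, network_tests, gaps, metadata,
    )


def _network_stage(table, networks, scores_all, cfg, seed, gaps) -> dict:
    out: dict = {}
    ids = _roster_ids(table, "adult_females")
    if len(ids) < 4:
        ids = table.ids
    kin = networks.get("kinship")
    groom = networks.get("grooming")
    share = networks.get("sharing")
    co = networks.get("co_observation")

    def transformed(m: DyadicMatrix) -> DyadicMatrix:
        r = m.reorder(ids)
        vals = np.log1p(r.values)
        np.fill_diagonal(vals, 0.0)
        return DyadicMatrix(ids, vals, r.kind, r.symmetric)

    rankd = net.rank_difference_matrices(scores_all, ids=ids)
    seeds = iter(np.random.default_rng(seed).integers(2**31, size=16))

    if kin is not None and groom is not None and share is not None:
        try:
            conflict = conflict_matrix_from_events(table, ids=ids)
            res = net.conflict_predictors(
                conflict, kin.reorder(ids), transformed(groom), transformed(share),
                co.reorder(ids) if co is not None else None,
                n_perm=cfg.n_perm, seed=int(next(seeds)),
            )
            out["conflict_predictors"] = {k: v.to_dict() for k, v in res.items()}
        except ValueError as exc:
            gaps.append(f"conflict_predictors: {exc}")
    else:
        gaps.append("conflict_predictors: kinship/grooming/sharing not all supplied")

    for label, mat in (("grooming", groom), ("sharing", share)):
        if mat is None:
            gaps.append(f"{label}: matrix not supplied")
            continue
        H = transformed(mat)
        received = DyadicMatrix(ids, H.values.T, f"{label}_received", H.symmetric)
        for diff_label, diff_key in (("signed", "signed"), ("up_only", "up_only"),
                                     ("absolute", "absolute")):
            res = net.mrqap_dsp(
                H, [received, rankd[diff_key]],
                n_perm=cfg.n_perm, seed=int(next(seeds)),
                names=["reciprocal", f"rank_diff_{diff_label}"],
            )
            out[f"{label}_given_vs_{diff_label}_rank_diff"] = {
                k: v.to_dict() for k, v in res.items()
            }
        sym = net.help_symmetry(mat.reorder(ids))
        vals = np.nan_to_num(sym.values, nan=0.0)
        np.fill_diagonal(vals, 0.0)
        sym_filled = DyadicMatrix(ids, vals, "help_symmetry", symmetric=True)
        out[f"{label}_symmetry_vs_abs_rank_diff"] = net.mantel(
            sym_filled, rankd["absolute"], n_perm=cfg.n_perm,
            seed=int(next(seeds)),
        ).to_dict()
        direc = net.help_directionality(
            mat.reorder(ids), scores_all, n_boot=cfg.n_boot, seed=int(next(seeds))
        )
        out[f"{label}_directionality"] = {
            "prop_up_mean": direc.prop_up_mean,
            "prop_up_ci": list(direc.prop_up_ci),
            "updown_mean": direc.updown_mean,
            "updown_ci": list(direc.updown_ci),
            "n_excluded": len(direc.excluded),
            "n_boot": direc.n_boot,
        }
    return out


def report_to_files(report: AnalysisReport, outdir) -> list[str]:
    """Write the report as one JSON plus TSVs per result family.

    Returns the list of files written; a ``manifest.json`` records both
    the files and the gaps (sections skipped for lack of inputs).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def w(name: str, obj) -> None:
        path = outdir / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, sep="\t", index=False)
        else:
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        written.append(name)

    w("report.json", report.to_dict())
    w("davids.tsv", report.davids)
    w("ranks.tsv", report.ranks)
    w("shape.tsv", report.shape)
    rows = []
    for roster, per_type in report.group_metrics.items():
        for label, metrics_ in per_type.items():
            for metric, d in metrics_.items():
                rows.append({"roster": roster, "events": label, "metric": metric, **d})
    if rows:
        w("group_metrics.tsv", pd.DataFrame(rows))
    w(
        "manifest.json",
        {"files": sorted(written + ["manifest.json"]), "gaps": report.gaps,
         "stage_seeds": report.metadata["stage_seeds"]},
    )
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
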