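"""Orchestration of the full coverage study.

One seed set is drawn from the master seed and reused by every generation
method.  For each (method, seed) pair a synthetic table of the same size
as the actual table is produced, and for each endpoint the synthetic
median survival time (MSTS) and the hazard-ratio distance (HRD) against
the actual data are recorded.  The headline summary is the coverage
table: for each method and endpoint, the number and proportion of
replicate medians falling inside the 95% CI of the actual median (MSTA).
Best and worst cases per method/endpoint are the replicates with the
highest and lowest HRD; their synthetic tables are re-synthesized
deterministically from their seeds for Kaplan-Meier overlays and log-rank
tests against the actual data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .data import RunConfig, TrialTable
from .metrics import MedianEstimate, cox_hr, hrd, km_curve, logrank_test, median_survival
from .synthesis import SynthesisError, get_generator, make_seed_set

logger = logging.getLogger("synthtrial")

ENDPOINTS = ("pfs", "os")


@dataclass(frozen=True)
class ReplicateRecord:
    method: str
    index: int  # replicate index (position in the shared seed list)
    seed: int
    endpoint: str
    mst: MedianEstimate | None
    hr: float | None
    hrd: float | None
    within_ci: bool | None  # None when MSTS undefined or actual CI open-ended
    failed: bool = False


@dataclass
class StudyResult:
    actual: TrialTable
    config: RunConfig
    seeds: list[int]
    msta: dict[str, MedianEstimate]
    replicates: list[ReplicateRecord]
    coverage: dict[tuple[str, str], dict]
    extremes: dict[tuple[str, str], dict]

    def replicate_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "method": r.method,
                "index": r.index,
                "seed": r.seed,
                "endpoint": r.endpoint,
                "mst": None if r.mst is None else r.mst.mst,
                "hr": r.hr,
                "hrd": r.hrd,
                "within_ci": r.within_ci,
                "failed": r.failed,
            }
            for r in self.replicates]
        )


def _within(msta: MedianEstimate, msts: MedianEstimate) -> bool | None:
    """Inclusive CI coverage of the synthetic median; None if undecidable."""
    if msts.mst is None or msta.ci_low is None or msta.ci_high is None:
        return None
    return bool(msta.ci_low <= msts.mst <= msta.ci_high)


def run_study(
    actual: TrialTable,
    methods: list[str] | tuple[str, ...],
    config: RunConfig,
    checkpoint_path: str | Path | None = None,
) -> StudyResult:
    """Run the seeded multi-replicate synthesis-and-evaluation study.

    Fully deterministic given ``config.master_seed``: the seed list, every
    synthetic table, and all tallies reproduce exactly.  A replicate whose
    synthesis exhausts its regeneration budget is recorded as failed and
    excluded from coverage denominators, with a warning.

    When ``checkpoint_path`` is given, per-replicate metrics are appended
    to that CSV as they complete, and on restart already-checkpointed
    (method, index, endpoint) rows are reused instead of recomputed.
    """
    seeds = make_seed_set(config.master_seed, config.n_replicates)
    msta = {
        ep: median_survival(km_curve(*actual.endpoint(ep)), config.conf_level)
        for ep in ENDPOINTS
    }
    for ep in ENDPOINTS:
        m = msta[ep]
        logger.info(
            "actual %s median %.1f d (CI %s-%s)", ep,
            math.nan if m.mst is None else m.mst, m.ci_low, m.ci_high,
        )

    done: dict[tuple[str, int, str], ReplicateRecord] = {}
    ckpt_fh = None
    if checkpoint_path is not None:
        checkpoint_path = Path(checkpoint_path)
        if checkpoint_path.exists():
            prev = pd.read_csv(checkpoint_path)
            for row in prev.to_dict("records"):
                rec = ReplicateRecord(
                    row["method"], int(row["index"]), int(row["seed"]), row["endpoint"],
                    None if pd.isna(row["mst"]) else MedianEstimate(float(row["mst"]), None, None, config.conf_level),
                    None if pd.isna(row["hr"]) else float(row["hr"]),
                    None if pd.isna(row["hrd"]) else float(row["hrd"]),
                    None if pd.isna(row["within_ci"]) else str(row["within_ci"]) == "True",
                    str(row["failed"]) == "True",
                )
                done[(rec.method, rec.index, rec.endpoint)] = rec
        else:
            checkpoint_path.write_text("method,index,seed,endpoint,mst,hr,hrd,within_ci,failed\n")
        ckpt_fh = open(checkpoint_path, "a")

    def checkpoint(rec: ReplicateRecord) -> None:
        if ckpt_fh is not None:
            mst = "" if rec.mst is None or rec.mst.mst is None else repr(rec.mst.mst)
            hr = "" if rec.hr is None else repr(rec.hr)
            hd = "" if rec.hrd is None else repr(rec.hrd)
            wc = "" if rec.within_ci is None else rec.within_ci
            ckpt_fh.write(f"{rec.method},{rec.index},{rec.seed},{rec.endpoint},{mst},{hr},{hd},{wc},{rec.failed}\n")

    replicates: list[ReplicateRecord] = []
    actual_ep = {ep: actual.endpoint(ep) for ep in ENDPOINTS}
    try:
        for method in methods:
            gen = get_generator(method)
            gen.fit(actual)
            n_failed = 0
            for i, seed in enumerate(seeds):
                key0 = (method, i, "pfs")
                if key0 in done and (method, i, "os") in done:
                    replicates.append(done[key0])
                    replicates.append(done[(method, i, "os")])
                    continue
                try:
                    synth = gen.sample(actual.n, seed)
                except SynthesisError as exc:
                    n_failed += 1
                    logger.warning("replicate %s/%d failed: %s", method, i, exc)
                    for ep in ENDPOINTS:
                        rec = ReplicateRecord(method, i, seed, ep, None, None, None, None, failed=True)
                        replicates.append(rec)
                        checkpoint(rec)
                    continue
                for ep in ENDPOINTS:
                    s_ep = synth.endpoint(ep)
                    med = median_survival(km_curve(*s_ep), config.conf_level)
                    hr = cox_hr(actual_ep[ep], s_ep)
                    rec = ReplicateRecord(
                        method, i, seed, ep, med, hr, hrd(hr), _within(msta[ep], med)
                    )
                    replicates.append(rec)
                    checkpoint(rec)
                if (i + 1) % 100 == 0:
                    logger.info("%s: %d/%d replicates done", method, i + 1, len(seeds))
            if n_failed:
                logger.warning(
                    "%s: %d/%d replicates failed synthesis and were excluded "
                    "from coverage denominators", method, n_failed, len(seeds),
                )
    finally:
        if ckpt_fh is not None:
            ckpt_fh.close()

    coverage: dict[tuple[str, str], dict] = {}
    for method in methods:
        for ep in ENDPOINTS:
            recs = [r for r in replicates if r.method == method and r.endpoint == ep]
            ok = [r for r in recs if not r.failed]
            count = sum(1 for r in ok if r.within_ci is True)
            coverage[(method, ep)] = {
                "count": count,
                "n": len(ok),
                "n_failed": len(recs) - len(ok),
                "proportion": count / len(ok) if ok else float("nan"),
            }

    result = StudyResult(actual, config, seeds, msta, replicates, coverage, {})
    for method in methods:
        for ep in ENDPOINTS:
            result.extremes[(method, ep)] = _extremes_for(result, method, ep)
    return result


def _extremes_for(result: StudyResult, method: str, endpoint: str) -> dict:
    recs = [
        r for r in result.replicates
        if r.method == method and r.endpoint == endpoint and not r.failed and r.hrd is not None
    ]
    if not recs:
        return {}
    # ties broken toward the smallest replicate index
    best = max(recs, key=lambda r: (r.hrd, -r.index))
    worst = min(recs, key=lambda r: (r.hrd, r.index))
    return {"best_index": best.index, "best_seed": best.seed, "best_hrd": best.hrd,
            "worst_index": worst.index, "worst_seed": worst.seed, "worst_hrd": worst.hrd}


def select_extremes(
    result: StudyResult, method: str, endpoint: Literal["pfs", "os"]
) -> dict:
    """Best/worst-case replicates by HRD, with their log-rank p vs actual.

    The synthetic tables are re-synthesized deterministically from the
    stored seeds; with a single successful replicate best and worst
    coincide.
    """
    ext = dict(result.extremes.get((method, endpoint)) or _extremes_for(result, method, endpoint))
    if not ext:
        raise ValueError(f"no successful replicate for {method}/{endpoint}")
    gen = get_generator(method)
    gen.fit(result.actual)
    a = result.actual.endpoint(endpoint)
    for which in ("best", "worst"):
        synth = gen.sample(result.actual.n, ext[f"{which}_seed"])
        stat, p = logrank_test(a, synth.endpoint(endpoint))
        ext[f"{which}_logrank_stat"] = stat
        ext[f"{which}_logrank_p"] = p
        ext[f"{which}_table"] = synth
    return ext


def coverage_table(result: StudyResult) -> pd.DataFrame:
    """Coverage summary: one row per method x endpoint, Table-style formatting.

    ``count_percent`` renders the count with the percentage in parentheses,
    e.g. ``981 (98.1)``.  Failed replicates reduce ``n`` and are reported
    in ``n_failed``.
    """
    rows = []
    for (method, ep), cov in sorted(result.coverage.items()):
        m = result.msta[ep]
        pct = 100.0 * cov["proportion"]
        fmt = (lambda v: "NA" if v is None else f"{v:.0f}")
        rows.append(
            {
                "method": method,
                "endpoint": ep,
                "count": cov["count"],
                "n": cov["n"],
                "n_failed": cov["n_failed"],
                "proportion": cov["proportion"],
                "count_percent": f"{cov['count']} ({pct:.1f})",
                "msta": m.mst,
                "msta_ci": f"{fmt(m.mst)} ({fmt(m.ci_low)}-{fmt(m.ci_high)})",
            }
        )
    return pd.DataFrame(rows)


def write_coverage_csv(result: StudyResult, path: str | Path) -> None:
    coverage_table(result).to_csv(path, index=False, lineterminator="\n")
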