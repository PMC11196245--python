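"""Figure rendering for a completed study.

Three figure families mirror the standard presentation of a
synthetic-data coverage study:

* per-method histograms of the synthetic median survival times, with the
  actual median as a dashed vertical line and its 95% CI as a shaded band,
* Kaplan-Meier overlays of the actual data with the best- and worst-case
  synthetic replicates (three curves per panel), annotated with log-rank
  p-values,
* box plots of the HRD distribution per method.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import km_curve
from .study import ENDPOINTS, StudyResult, select_extremes

__all__ = ["render_figures"]


def _km_steps(times, events):
    curve = km_curve(times, events)
    t = np.concatenate([[0.0], curve.event_times])
    s = np.concatenate([[1.0], curve.survival])
    return t, s


def _plot_km(ax, times, events, label, **kw):
    t, s = _km_steps(times, events)
    ax.step(t, s, where="post", label=label, **kw)


def render_figures(result: StudyResult, outdir: str | Path) -> list[Path]:
    """Render all figure families into ``outdir``; returns the file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    methods = sorted({r.method for r in result.replicates})
    written: list[Path] = []

    # 1) MSTS histograms with the MSTA line and CI band
    for ep in ENDPOINTS:
        msta = result.msta[ep]
        fig, axes = plt.subplots(
            1, len(methods), figsize=(4.2 * len(methods), 3.4), squeeze=False, sharex=True
        )
        for ax, method in zip(axes[0], methods):
            msts = [
                r.mst.mst
                for r in result.replicates
                if r.method == method and r.endpoint == ep and not r.failed
                and r.mst is not None and r.mst.mst is not None
            ]
            lo = min([msta.ci_low or np.inf, *(msts or [np.inf])])
            hi = max([msta.ci_high or -np.inf, *(msts or [-np.inf])])
            pad = 0.05 * max(hi - lo, 1.0)
            if msts:
                ax.hist(msts, bins=30, range=(lo - pad, hi + pad), color="0.55")
            if msta.ci_low is not None and msta.ci_high is not None:
                ax.axvspan(msta.ci_low, msta.ci_high, color="lightblue", alpha=0.5, zorder=0)
            if msta.mst is not None:
                ax.axvline(msta.mst, color="k", linestyle="--")
            ax.set_title(f"{method} / {ep.upper()}")
            ax.set_xlabel("median survival time (days)")
            ax.set_xlim(lo - pad, hi + pad)
        axes[0][0].set_ylabel("replicates")
        fig.tight_layout()
        path = outdir / f"hist_msts_{ep}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    # 2) KM overlays: actual + best case + worst case (3 curves per panel)
    for ep in ENDPOINTS:
        fig, axes = plt.subplots(
            1, len(methods), figsize=(4.2 * len(methods), 3.4), squeeze=False, sharey=True
        )
        for ax, method in zip(axes[0], methods):
            try:
                ext = select_extremes(result, method, ep)
            except ValueError:
                ax.set_axis_off()
                continue
            _plot_km(ax, *result.actual.endpoint(ep), "actual", color="k")
            _plot_km(ax, *ext["best_table"].endpoint(ep),
                     f"best (p={ext['best_logrank_p']:.2f})", color="tab:blue")
            _plot_km(ax, *ext["worst_table"].endpoint(ep),
                     f"worst (p={ext['worst_logrank_p']:.2f})", color="tab:red")
            ax.set_title(f"{method} / {ep.upper()}")
            ax.set_xlabel("days")
            ax.legend(fontsize=8)
        axes[0][0].set_ylabel("survival probability")
        fig.tight_layout()
        path = outdir / f"km_extremes_{ep}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    # 3) HRD box plots per method
    for ep in ENDPOINTS:
        fig, ax = plt.subplots(figsize=(1.6 + 1.3 * len(methods), 3.4))
        data = [
            [r.hrd for r in result.replicates
             if r.method == m and r.endpoint == ep and not r.failed and r.hrd is not None]
            for m in methods
        ]
        ax.boxplot(data, tick_labels=methods)
        ax.axhline(1.0, color="0.6", linestyle=":")
        ax.set_ylabel("HRD")
        ax.set_title(f"HRD by method / {ep.upper()}")
        fig.tight_layout()
        path = outdir / f"hrd_box_{ep}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    return written
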