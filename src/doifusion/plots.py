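"""Optional matplotlib figures: Bland-Altman, ROC, AUC-vs-threshold.

Imported lazily by the CLI so the core pipeline has no plotting
dependency.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .agreement import AgreementReport
from .fusion import GridSearchResult
from .roc import RocReport


def _ax():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def bland_altman_plot(measure, reference, report: AgreementReport, path, title=""):
    plt = _ax()
    measure = np.asarray(measure, float)
    reference = np.asarray(reference, float)
    means = (measure + reference) / 2
    diffs = measure - reference
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=18, color="black")
    ax.axhline(report.bias, color="red", label=f"bias {report.bias:.2f} mm")
    for y in (report.loa_low, report.loa_high):
        ax.axhline(y, color="blue", linestyle="--")
    ax.set_xlabel("mean of imaging and pathology DOI (mm)")
    ax.set_ylabel("imaging − pathology (mm)")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def roc_plot(report: RocReport, path, title=""):
    plt = _ax()
    arr = report.curve_array()
    fig, ax = plt.subplots(figsize=(4.2, 4))
    ax.plot(arr[:, 0], arr[:, 1], color="black", drawstyle="default")
    ax.plot([0, 1], [0, 1], color="grey", linestyle=":")
    ax.set_xlabel("1 − specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"{title} AUC={report.auc:.3f}, cutoff={report.optimal_cutoff:.1f} mm")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def grid_plot(result: GridSearchResult, path, title="AUC vs switching threshold"):
    plt = _ax()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(result.candidate_thresholds, result.auc_per_threshold, marker="o", color="black")
    ax.axvline(result.best_threshold, color="red", linestyle="--",
               label=f"best {result.best_threshold:.2f} mm (AUC {result.best_auc:.3f})")
    ax.set_xlabel("usDOI switching threshold (mm)")
    ax.set_ylabel("AUC of composite us/mrDOI")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
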