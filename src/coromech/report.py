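"""Deterministic regeneration of figures and tables from stored run artifacts.

A completed run directory contains CSV/JSON artifacts written by the CLI
subcommands (simulated measurements, reduced and fitted stresses,
transmural profiles).  ``report`` re-reads them and writes vector-graphics
figures alongside; it performs no computation beyond plotting, so
re-running it on the same inputs produces identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

# reproducible SVG output: fixed hash salt, no timestamps
plt.rcParams["svg.hashsalt"] = "coromech"

__all__ = ["report", "provenance_header"]

#: artifact filenames a run directory may contain, with the figure each yields
_KNOWN = {
    "fitted_vs_experimental.csv": "stress_fit.svg",
    "transmural_profile.csv": "transmural.svg",
    "sensitivity.csv": "sensitivity.svg",
}


def provenance_header(inputs: dict) -> str:
    """Provenance comment block for output files: inputs, config and seed."""
    lines = [f"# {k}: {v}" for k, v in sorted(inputs.items())]
    return "\n".join(lines) + "\n"


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def report(run_dir) -> list:
    """Regenerate figures for every known artifact in ``run_dir``.

    Returns the list of files written.  Raises FileNotFoundError naming the
    expected artifacts when none is present.
    """
    run_dir = Path(run_dir)
    present = [name for name in _KNOWN if (run_dir / name).exists()]
    if not present:
        raise FileNotFoundError(
            f"no reportable artifacts in {run_dir}; expected one of: "
            f"{', '.join(sorted(_KNOWN))}"
        )
    written = []
    meta = {}
    meta_path = run_dir / "run.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())

    for name in present:
        df = _read_csv(run_dir / name)
        out = run_dir / _KNOWN[name]
        fig, ax = plt.subplots(figsize=(5, 3.5), constrained_layout=True)
        if name == "fitted_vs_experimental.csv":
            for comp, marker in (("T_theta", "s"), ("T_z", "^"), ("T_r", "o")):
                ax.plot(df["lam_theta"], df[f"{comp}_exp_kPa"], marker, ms=3,
                        ls="none", label=f"{comp} exp")
                ax.plot(df["lam_theta"], df[f"{comp}_fit_kPa"], "-", lw=1,
                        label=f"{comp} fit")
            ax.set_xlabel(r"$\lambda_\theta$")
            ax.set_ylabel("1st PK stress (kPa)")
        elif name == "transmural_profile.csv":
            ax.plot(df["x_norm"], df["sigma_theta_kPa"], label=r"$\sigma_\theta$")
            ax.plot(df["x_norm"], df["sigma_r_kPa"], label=r"$\sigma_r$")
            ax.set_xlabel("normalized wall coordinate")
            ax.set_ylabel("Cauchy stress (kPa)")
        else:  # sensitivity.csv
            for m, grp in df.groupby("multiplier"):
                ax.plot(grp["lam_theta"], grp["value_kPa"], label=f"x{m:g}")
            ax.set_xlabel(r"$\lambda_\theta$")
            ax.set_ylabel("active 1st PK stress (kPa)")
        ax.legend(fontsize=7)
        title = meta.get("title", "")
        if title:
            ax.set_title(title, fontsize=9)
        fig.savefig(out, metadata={"Date": None})
        plt.close(fig)
        written.append(out)
    return written
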