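"""Rate-characteristic plots (log-log block fluxes vs the clamped variable).

Plots are vector graphics with a JSON sidecar of every plotted number, so
tests and downstream tooling assert on data rather than pixels.  Because
block fluxes can cross zero inside a scan (a block passing through
equilibrium), curves show ``|J|`` with sign-change markers.
"""

from __future__ import annotations

import json
import math
from typing import Optional

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from gsda.blocks import SupplyDemandScan


def _tangent_segment(x0: float, y0: float, slope: float, half_decades: float = 0.4):
    """A straight segment in log-log space through (x0, |y0|) with the given
    log-log slope (= the response coefficient)."""
    f = 10.0 ** half_decades
    xs = np.array([x0 / f, x0 * f])
    ys = abs(y0) * (xs / x0) ** slope
    return xs, ys


def plot_rate_characteristic(
    scan: SupplyDemandScan,
    path: Optional[str] = None,
    tangents: bool = True,
    tangent_blocks: Optional[list] = None,
    title: Optional[str] = None,
):
    """Render one scan; returns ``(figure, sidecar)`` and optionally writes
    ``<path>.svg`` plus ``<path>.json``."""
    conv = [r for r in scan.records if r.converged]
    if len(conv) < 2:
        raise ValueError("need at least 2 converged scan points to plot")
    x = np.array([r.value for r in conv])

    sidecar = {
        "clamped": scan.clamped,
        "ref_value": scan.ref_value,
        "curves": {},
        "tangents": {},
    }
    fig, ax = plt.subplots(figsize=(6.0, 4.5))
    for b in scan.blocks:
        J = np.array([r.block_flux(b) for r in conv])
        label = f"J_{b.name} ({b.kind})"
        ax.plot(x, np.abs(J), label=label)
        flips = np.where(np.sign(J[:-1]) * np.sign(J[1:]) < 0)[0]
        if flips.size:
            ax.plot(x[flips], np.abs(J[flips]), "kx", markersize=6)
        sidecar["curves"][b.name] = {
            "kind": b.kind,
            "x": x.tolist(),
            "J": J.tolist(),
            "sign_changes": x[flips].tolist(),
        }
    for kind in ("supply", "demand"):
        if sum(b.kind == kind for b in scan.blocks) > 1:
            adj = {b.adjacent_reaction for b in scan.blocks if b.kind == kind}
            total = np.array([sum(r.fluxes[a] for a in sorted(adj)) for r in conv])
            ax.plot(x, np.abs(total), "--", label=f"total {kind}")
            sidecar["curves"][f"total_{kind}"] = {"kind": kind, "x": x.tolist(),
                                                  "J": total.tolist()}

    ref = scan.reference_record
    if tangents and ref.converged:
        for b in scan.blocks:
            if tangent_blocks is not None and b.name not in tangent_blocks:
                continue
            resp = ref.responses.get(b.name)
            if resp is None or math.isnan(resp.value):
                continue
            J0 = ref.block_flux(b)
            xs, ys = _tangent_segment(ref.value, J0, resp.value)
            ax.plot(xs, ys, "--", color="0.3", linewidth=1)
            entry = {"total": resp.value, "partials": {}}
            for rxn, p in resp.decomposition.items():
                xs, ys = _tangent_segment(ref.value, J0, p, half_decades=0.25)
                ax.plot(xs, ys, "-", color="0.6", linewidth=0.8)
                entry["partials"][rxn] = p
            sidecar["tangents"][b.name] = entry

    ax.axvline(scan.ref_value, linestyle=":", color="k", linewidth=1)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(scan.clamped)
    ax.set_ylabel("|J|")
    ax.set_title(title or f"Rate characteristic: {scan.clamped}")
    ax.legend(fontsize=8)
    fig.tight_layout()

    if path is not None:
        fig.savefig(f"{path}.svg", format="svg")
        with open(f"{path}.json", "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh, indent=1)
    return fig, sidecar
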