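"""Tabular output: scan tables and coefficient tables as TSV/JSON.

TSV (tab-separated, UTF-8, Unix newlines) avoids locale decimal trouble;
floats are serialised at 17 significant digits so write-read round-trips
are bit-exact, and flagged/unavailable entries are the literal ``NaN``.
"""

from __future__ import annotations

import json
import math
from typing import Union

import pandas as pd

from gsda.blocks import SupplyDemandScan
from gsda.mca import ControlMatrices


def scan_to_frame(scan: SupplyDemandScan) -> pd.DataFrame:
    """One row per grid point: ``scan_value, converged, J_<block>...,
    R_<block>..., pR_<block>__via_<rxn>..., C_<block>__<rxn>..., eps_<rxn>...``."""
    partial_rxns: dict = {b.name: set() for b in scan.blocks}
    eps_rxns: set = set()
    for rec in scan.records:
        for bname, resp in rec.responses.items():
            partial_rxns[bname] |= set(resp.decomposition)
            eps_rxns |= set(resp.factors)

    columns = ["scan_value", "converged"]
    columns += [f"J_{b.name}" for b in scan.blocks]
    columns += [f"R_{b.name}" for b in scan.blocks]
    for b in scan.blocks:
        columns += [f"pR_{b.name}__via_{r}" for r in sorted(partial_rxns[b.name])]
    for b in scan.blocks:
        columns += [f"C_{b.name}__{r}" for r in sorted(partial_rxns[b.name])]
    columns += [f"eps_{r}" for r in sorted(eps_rxns)]

    rows = []
    for rec in scan.records:
        row = {"scan_value": rec.value, "converged": int(rec.converged)}
        for b in scan.blocks:
            row[f"J_{b.name}"] = rec.block_flux(b) if rec.converged else math.nan
            resp = rec.responses.get(b.name)
            row[f"R_{b.name}"] = resp.value if resp else math.nan
            for r in sorted(partial_rxns[b.name]):
                row[f"pR_{b.name}__via_{r}"] = (
                    resp.decomposition.get(r, math.nan) if resp else math.nan)
                row[f"C_{b.name}__{r}"] = (
                    resp.factors[r][0] if resp and r in resp.factors else math.nan)
        eps_row = {}
        for resp in rec.responses.values():
            for r, (_, eps) in resp.factors.items():
                eps_row[r] = eps
        for r in sorted(eps_rxns):
            row[f"eps_{r}"] = eps_row.get(r, math.nan)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=columns)
    assert frame["scan_value"].is_monotonic_increasing
    return frame


def write_tsv(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.17g",
                 na_rep="NaN", lineterminator="\n")


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col,
                       float_precision="round_trip")


def write_scan_tsv(scan: Union[SupplyDemandScan, pd.DataFrame], path) -> None:
    frame = scan if isinstance(scan, pd.DataFrame) else scan_to_frame(scan)
    write_tsv(frame, path)


def control_matrices_to_json(cm: ControlMatrices) -> dict:
    """Nested mappings at full precision (floats survive JSON round-trip)."""
    return {
        "flux_control": {i: {c: float(cm.flux_control.loc[i, c])
                             for c in cm.flux_control.columns}
                         for i in cm.flux_control.index},
        "conc_control": {i: {c: float(cm.conc_control.loc[i, c])
                             for c in cm.conc_control.columns}
                         for i in cm.conc_control.index},
        "theorems": cm.theorems,
        "zero_flux": sorted(cm.zero_flux),
    }


def write_control_matrices(cm: ControlMatrices, tsv_prefix=None, json_path=None) -> None:
    if tsv_prefix is not None:
        write_tsv(cm.flux_control, f"{tsv_prefix}_flux_control.tsv", index=True)
        write_tsv(cm.conc_control, f"{tsv_prefix}_conc_control.tsv", index=True)
    if json_path is not None:
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(control_matrices_to_json(cm), fh, indent=1)


def route_shares_to_json(shares) -> dict:
    return {
        s.name: {
            "chi_percent": s.chi,
            "chi_percent_abs": s.chi_abs,
            "target_block": s.target_block,
            "stage1_partials": list(s.stage1_group),
            "stage2_partials": list(s.stage2_group),
            "stage1_fraction": s.stage1_fraction,
            "stage2_fraction": s.stage2_fraction,
        }
        for s in shares
    }
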