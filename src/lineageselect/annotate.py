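"""Proximity of positively selected residues to annotated variant positions.

Positively selected sites, once mapped to reference-sequence numbering, are
related to user-supplied variant/feature positions by absolute residue
distance within a window.  No enrichment statistic is computed — with a
handful of sites per gene the coincidences are descriptive; a permutation
enrichment test is a deliberate extension point.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

_VARIANT_COLUMNS = ["residue", "label", "category"]


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a variant/feature TSV with columns residue, label, category."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _VARIANT_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    if "category" not in df.columns:
        df["category"] = ""
    return validate_variant_table(df)


def validate_variant_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["residue"] = df["residue"].astype(int)
    if (df["residue"] < 1).any():
        raise ValueError("variant residues must be >= 1")
    if df["label"].astype(str).str.len().eq(0).any():
        raise ValueError("variant labels must be non-empty")
    return df


def proximity_report(sites: list[int], variants: pd.DataFrame,
                     window: int = 10) -> pd.DataFrame:
    """One record per (site, variant) pair within ``window`` residues.

    ``sites`` are reference-mapped residue numbers.  Distance is the
    absolute residue difference; enlarging the window never removes records.
    Empty inputs yield an empty report.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    records = []
    if len(variants):
        variants = validate_variant_table(variants)
        for site in sites:
            for _, var in variants.iterrows():
                distance = abs(int(site) - int(var["residue"]))
                if distance <= window:
                    records.append({
                        "site": int(site),
                        "variant_label": str(var["label"]),
                        "variant_residue": int(var["residue"]),
                        "category": str(var.get("category", "")),
                        "distance": distance,
                        "window": window,
                    })
    return pd.DataFrame(records, columns=["site", "variant_label",
                                          "variant_residue", "category",
                                          "distance", "window"])
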