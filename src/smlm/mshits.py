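"""Filtering and scoring of mass-spectrometry pull-down hit tables.

Hit tables carry one row per identified protein with the X! Tandem
log-expectation score (``log_e``), peptide counts and molecular weight.
Top hits are those passing, within a replicate, the conjunction
``log_e <= -10 AND total_peptides >= 5 AND unique_peptides >= 2``, in at
least two independent replicate experiments; any protein observed in a
"no bait" control (any observation, the stricter reading) is excluded.
``peptide_density`` is the total-peptides / molecular-weight column used
to rank hits by sequence coverage per unit mass.

The galectin-9 pull-down summary table is shipped as package data and
loadable with :func:`load_gal9_hits`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["peptide_density", "filter_hits", "load_gal9_hits"]

REQUIRED = ["uniprot", "log_e", "unique_peptides", "total_peptides", "mr"]


def peptide_density(total_peptides: float, mr: float) -> float:
    """Total peptides per kDa of molecular weight."""
    if mr <= 0:
        raise ValueError("molecular weight must be positive")
    return total_peptides / mr


def load_gal9_hits() -> pd.DataFrame:
    """The published galectin-9 pull-down summary table (one replicate)."""
    with resources.files("smlm.data").joinpath("gal9_pulldown_hits.csv").open() as fh:
        return pd.read_csv(fh)


def _passes(df: pd.DataFrame, log_e_max, min_total, min_unique):
    return (
        (df["log_e"] <= log_e_max)
        & (df["total_peptides"] >= min_total)
        & (df["unique_peptides"] >= min_unique)
    )


def filter_hits(replicates, no_bait=(), log_e_max: float = -10.0,
                min_total: int = 5, min_unique: int = 2,
                min_replicates: int = 2) -> pd.DataFrame:
    """Accepted hits across replicate pull-down experiments.

    ``replicates`` is a sequence of >= 2 hit DataFrames (one per
    independent experiment); ``no_bait`` a sequence of control DataFrames.
    A protein (keyed on UniProt accession) is accepted when the
    three-criteria conjunction holds in at least ``min_replicates``
    replicates and the protein appears in no control.  The output is
    annotated with the per-replicate pass count and peptide density
    (computed from the replicate with the best ``log_e``).
    """
    replicates = list(replicates)
    if len(replicates) < min_replicates:
        raise ValueError(
            f"need at least {min_replicates} replicate experiments, "
            f"got {len(replicates)}"
        )
    for df in replicates:
        missing = [c for c in REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"hit table missing columns {missing}")
    excluded = set()
    for ctrl in no_bait:
        excluded.update(ctrl["uniprot"])
    pass_counts = {}
    best = {}
    for df in replicates:
        ok = _passes(df, log_e_max, min_total, min_unique)
        for _, row in df.loc[ok].iterrows():
            uid = row["uniprot"]
            pass_counts[uid] = pass_counts.get(uid, 0) + 1
            if uid not in best or row["log_e"] < best[uid]["log_e"]:
                best[uid] = row
    rows = []
    for uid, cnt in pass_counts.items():
        if cnt >= min_replicates and uid not in excluded:
            row = best[uid].copy()
            row["n_passing_replicates"] = cnt
            row["peptide_density"] = peptide_density(
                row["total_peptides"], row["mr"]
            )
            rows.append(row)
    if not rows:
        return pd.DataFrame(
            columns=REQUIRED + ["n_passing_replicates", "peptide_density"]
        )
    out = pd.DataFrame(rows).reset_index(drop=True)
    return out.sort_values("log_e").reset_index(drop=True)
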