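"""Reading and writing binding tables and catalogs (CSV and SDF V2000).

CSV is the canonical interchange format: UTF-8 with a header, columns
``id, formula (or smiles), mw, hac, ac`` plus passthrough columns such as
``p_mol``, ``target_class`` or ``price_per_g``.  Descriptors missing from
the file are computed from the structure column; when a file carries both a
formula and an MW column, the MW is recomputed and discrepancies beyond a
relative tolerance are reported rather than silently trusted.

SDF support covers V2000 records, with the molecule identifier taken from
the title line (or a property tag) and price/affinity read from named data
fields.  Reading goes through rdkit when a file contains real structures;
writing emits composition-only records (disconnected atoms, explicit
hydrogens, zero-valence flagged) since the descriptors here depend only on
composition.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .moltable import (
    FormulaError,
    compute_ac,
    compute_hac,
    compute_mw,
    counts_from_smiles,
    parse_formula,
)

logger = logging.getLogger(__name__)

MW_CHECK_RTOL = 1e-3  # catalog MW fields are often rounded to 2-3 decimals


def _counts_for_row(row: pd.Series):
    if "formula" in row.index and isinstance(row["formula"], str) and row["formula"]:
        return parse_formula(row["formula"])
    if "smiles" in row.index and isinstance(row["smiles"], str) and row["smiles"]:
        return counts_from_smiles(row["smiles"])
    return None


def add_descriptors(df: pd.DataFrame) -> pd.DataFrame:
    """Fill mw/hac/ac/brc from the structure column where possible.

    Rows without any structure keep whatever descriptor columns they came
    with.  When a stated MW disagrees with the recomputed one beyond
    ``MW_CHECK_RTOL`` relative, the recomputed value wins and the
    discrepancy count is logged.
    """
    df = df.copy()
    counts_list = [_counts_for_row(row) for _, row in df.iterrows()]
    have = [c is not None for c in counts_list]
    if not any(have):
        return df
    mw = np.array([compute_mw(c) if c else np.nan for c in counts_list])
    hac = np.array([compute_hac(c) if c else np.nan for c in counts_list])
    ac = np.array([compute_ac(c) if c else np.nan for c in counts_list])
    brc = np.array([c.get("Br", 0) if c else np.nan for c in counts_list])

    if "mw" in df.columns:
        stated = pd.to_numeric(df["mw"], errors="coerce").to_numpy()
        both = ~np.isnan(mw) & ~np.isnan(stated)
        mismatch = both & (np.abs(stated - mw) > MW_CHECK_RTOL * np.abs(mw))
        if mismatch.any():
            logger.warning(
                "%d stated MW values disagree with composition; recomputed "
                "values used", int(mismatch.sum()),
            )
    for col, values in (("mw", mw), ("hac", hac), ("ac", ac), ("brc", brc)):
        stated = (
            pd.to_numeric(df[col], errors="coerce").to_numpy()
            if col in df.columns else np.full(len(df), np.nan)
        )
        df[col] = np.where(np.isnan(values), stated, values)
    return df


def read_binding_csv(path: str | Path, p_col: str = "p_mol") -> pd.DataFrame:
    """Read a ligand binding table, computing descriptors as needed.

    Binding free energies are stored as magnitudes; negative inputs are
    negated with a logged count (a ΔG of −8 kcal/mol and its magnitude
    describe the same interaction strength).
    """
    df = pd.read_csv(path)
    df = add_descriptors(df)
    required = [p_col, "mw", "hac"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"binding table {path} lacks required columns {missing} "
            "(provide them directly or via a formula/smiles column)"
        )
    vals = pd.to_numeric(df[p_col], errors="coerce")
    n_neg = int((vals < 0).sum())
    if n_neg:
        logger.info("negating %d negative %s values to magnitudes", n_neg, p_col)
    df[p_col] = vals.abs()
    return df


def read_catalog_csv(path: str | Path) -> pd.DataFrame:
    """Read a priced catalog; requires price_per_g and mw (or structure)."""
    df = pd.read_csv(path)
    df = add_descriptors(df)
    missing = [c for c in ("price_per_g", "mw") if c not in df.columns]
    if missing:
        raise ValueError(f"catalog {path} lacks required columns {missing}")
    return df


# ---------------------------------------------------------------------------
# SDF V2000


def write_sdf(
    df: pd.DataFrame,
    path: str | Path,
    data_fields: tuple[str, ...] = ("price_per_g",),
) -> None:
    """Write composition-only V2000 SDF records.

    Each record lists its atoms (hydrogens explicit) at the origin with no
    bonds and the zero-valence flag set, so downstream toolkits do not
    invent implicit hydrogens; *data_fields* become SDF data items.
    """
    lines: list[str] = []
    for _, row in df.iterrows():
        counts = parse_formula(row["formula"])
        atoms: list[str] = []
        for symbol, n in counts.items():
            atoms.extend([symbol] * n)
        if len(atoms) > 999:
            raise ValueError(f"record {row.get('id')!r} exceeds V2000 atom limit")
        lines.append(str(row.get("id", "")))
        lines.append("  ligeff")  # program line
        lines.append("")
        lines.append(f"{len(atoms):3d}{0:3d}  0  0  0  0  0  0  0  0999 V2000")
        for symbol in atoms:
            lines.append(
                f"{0.0:10.4f}{0.0:10.4f}{0.0:10.4f} {symbol:<3} 0  0  0  0  0 15  0  0  0  0  0  0"
            )
        lines.append("M  END")
        for name in data_fields:
            if name in row.index and pd.notna(row[name]):
                lines.append(f">  <{name}>")
                lines.append(str(row[name]))
                lines.append("")
        lines.append("$$$$")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_sdf(
    path: str | Path,
    id_prop: str | None = None,
    data_fields: tuple[str, ...] = ("price_per_g",),
) -> pd.DataFrame:
    """Read a V2000 SDF into a descriptor table via rdkit.

    Implicit hydrogens are made explicit before counting so AC includes
    them; unreadable records are skipped with a logged count.
    """
    try:
        from rdkit import Chem
        from rdkit import RDLogger

        RDLogger.DisableLog("rdApp.*")
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError("SDF input requires rdkit (install the 'chem' extra)") from exc

    rows = []
    n_bad = 0
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            n_bad += 1
            continue
        mol = Chem.AddHs(mol)
        counts: dict[str, int] = {}
        for atom in mol.GetAtoms():
            counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        if id_prop and mol.HasProp(id_prop):
            mol_id = mol.GetProp(id_prop)
        elif mol.HasProp("_Name") and mol.GetProp("_Name"):
            mol_id = mol.GetProp("_Name")
        else:
            mol_id = f"SDF{i + 1:07d}"
        row = {
            "id": mol_id,
            "formula": "".join(
                f"{s}{counts[s]}" for s in sorted(counts, key=lambda s: (s != "C", s != "H", s))
            ),
            "mw": compute_mw(counts),
            "hac": compute_hac(counts),
            "ac": compute_ac(counts),
            "brc": counts.get("Br", 0),
        }
        for name in data_fields:
            if mol.HasProp(name):
                try:
                    row[name] = float(mol.GetProp(name))
                except ValueError:
                    row[name] = mol.GetProp(name)
        rows.append(row)
    if n_bad:
        logger.info("skipped %d unreadable SDF records", n_bad)
    if not rows:
        raise FormulaError(f"no readable records in {path}")
    return pd.DataFrame(rows)
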