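"""Machine-readable study tables and the prose-level consistency checks.

The package ships four reference CSVs under ``data/``:

* ``table1_obb.csv`` — OBB energies per cation and hydration pattern
  (``gas_ref`` holds earlier literature values computed with different
  software; stored for context, excluded from all checks);
* ``table2_components.csv`` — the five-component decomposition, E_Sum and
  E_binding per complex;
* ``table3_sapt.csv`` — SAPT components per cation and hydration site;
* ``centroid_distances.csv`` — cation–ring-centroid distances of the
  optimised 2- and 3-ring complexes.

Every qualitative claim the study tables support — OBB strength ordering
Li⁺ < Na⁺ < K⁺, cation-side hydration weakening vs ring-side hydration
strengthening, the destabilising (positive) water–water term — is encoded
here as a named boolean check over the shipped fixtures.  The "strength"
of an interaction is the absolute value of its (negative) energy; that
convention is encoded once in :func:`strength`.

Fixture files are integrity-checked by SHA-256 on load, so any drift
between the shipped bytes and the checks fails loudly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .decomposition import DecompositionResult
from .sapt import SaptComponents, load_sapt_csv

__all__ = [
    "FixtureTable",
    "strength",
    "load_table1",
    "load_table2",
    "load_table3",
    "load_distances",
    "table3_rows",
    "ordering_checks",
    "water_water_sign_check",
    "render_report",
]

EXPECTED_SHA256 = {
    "table1_obb.csv": "f0eb9598c58c827704517180bc3cb196623c124d241f5459e83768dea5640ab5",
    "table2_components.csv": "e2fce6fbd749b012957b5b693266dac5c2e9949830cea64cfe0504256a961e41",
    "table3_sapt.csv": "1ccd7afbf8058dc8ac4c65d8ea586eaaf70135a13acc2ac0abae57a0fcddc33b",
    "centroid_distances.csv": "c80b5d4aae5f37bfcdf4c675d983145ff7368221ce7318bf9d71f0ec1d74ec48",
}

CATION_ORDER = ("Li", "Na", "K")
T1_COLUMNS = ("gas", "coordinated", "hollow", "bridge", "total")


def strength(energy: float) -> float:
    """Interaction strength: |E| (a more negative energy is stronger)."""
    return abs(energy)


@dataclass(frozen=True)
class FixtureTable:
    """A shipped table: id, parsed frame, and the verbatim CSV text."""

    table_id: str
    frame: pd.DataFrame
    raw_text: str

    def reemit_csv(self, path=None) -> str:
        """The shipped CSV bytes, unchanged (round-trip guarantee)."""
        if path is not None:
            Path(path).write_text(self.raw_text)
        return self.raw_text


def _fixture_path(name: str):
    return resources.files("cation3pi").joinpath("data", name)


def _load(name: str, table_id: str) -> FixtureTable:
    text = _fixture_path(name).read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != EXPECTED_SHA256[name]:
        raise RuntimeError(
            f"fixture {name} failed its integrity check "
            f"(sha256 {digest[:12]}… != expected {EXPECTED_SHA256[name][:12]}…)"
        )
    from io import StringIO

    return FixtureTable(table_id, pd.read_csv(StringIO(text)), text)


def load_table1() -> FixtureTable:
    return _load("table1_obb.csv", "T1")


def load_table2() -> FixtureTable:
    return _load("table2_components.csv", "T2")


def load_table3() -> FixtureTable:
    return _load("table3_sapt.csv", "T3")


def load_distances() -> FixtureTable:
    return _load("centroid_distances.csv", "distances")


def table3_rows() -> list[SaptComponents]:
    """The SAPT fixture as verified :class:`SaptComponents` records."""
    with resources.as_file(_fixture_path("table3_sapt.csv")) as path:
        return load_sapt_csv(path)


def ordering_checks(t1: FixtureTable) -> dict[str, bool]:
    """Named boolean checks of the OBB-energy table.

    Columns: |OBB| strictly increasing Li → Na → K.  Rows: cation-side
    hydration (coordinated) weakens the binding relative to the gas phase
    (less negative OBB), ring-side hydration strengthens it, and the
    bridge site strengthens it beyond the hollow site.
    """
    df = t1.frame.set_index("cation")
    for col in T1_COLUMNS:
        if col not in df.columns or df[col].reindex(CATION_ORDER).isna().any():
            raise ValueError(f"OBB table is missing values in column {col!r}")
    report: dict[str, bool] = {}
    for col in T1_COLUMNS:
        li, na, k = (strength(df.loc[c, col]) for c in CATION_ORDER)
        report[f"strength_order_Li<Na<K[{col}]"] = bool(li < na < k)
    for cation in CATION_ORDER:
        row = df.loc[cation]
        report[f"coordinated_weaker_than_gas[{cation}]"] = bool(row["coordinated"] > row["gas"])
        report[f"hollow_stronger_than_gas[{cation}]"] = bool(row["hollow"] < row["gas"])
        report[f"bridge_stronger_than_hollow[{cation}]"] = bool(row["bridge"] < row["hollow"])
    return report


def water_water_sign_check(t2: FixtureTable) -> dict:
    """Sign audit of the water–water component across the component table.

    Water–water interactions are expected to destabilise (E_W-W ≥ 0);
    negative rows are reported as documented exceptions, and the largest
    positive value is flagged.
    """
    df = t2.frame
    signs = {}
    for rec in df.to_dict("records"):
        v = rec["e_water_water"]
        signs[rec["complex"]] = "neutral" if v == 0 else ("positive" if v > 0 else "negative")
    exceptions = [name for name, s in signs.items() if s == "negative"]
    nonneg = sum(1 for s in signs.values() if s != "negative")
    largest = df.loc[df["e_water_water"].idxmax()]
    return {
        "signs": signs,
        "n_rows": len(df),
        "n_nonnegative": nonneg,
        "exceptions": exceptions,
        "largest_positive": {
            "complex": largest["complex"],
            "e_water_water": float(largest["e_water_water"]),
        },
    }


def render_report(results, path_prefix=None) -> tuple[str, str]:
    """Deterministic Markdown + CSV rendering of analysis results.

    ``results`` may be a list of :class:`DecompositionResult` (one CSV row
    per complex, input order, 2-decimal floats) or a single
    :class:`FixtureTable` (re-emitted byte-for-byte).  Returns
    ``(markdown, csv_text)`` and optionally writes ``<prefix>.md`` /
    ``<prefix>.csv``.
    """
    if isinstance(results, FixtureTable):
        csv_text = results.reemit_csv()
        df = results.frame
        title = f"Fixture {results.table_id}"
    else:
        rows = [r.to_row() for r in results if isinstance(r, DecompositionResult)]
        df = pd.DataFrame(rows)
        title = "Decomposition results"
        if df.empty:
            csv_text = (
                "complex,e_cation_pi,e_pi_pi,e_water_pi,e_water_water,"
                "e_water_cation,e_sum,e_binding\n"
            )
        else:
            csv_text = df.to_csv(index=False, float_format="%.2f")

    lines = [f"# {title}", ""]
    if df.empty:
        lines.append("(no rows)")
    else:
        fmt = df.copy()
        for col in fmt.columns:
            if pd.api.types.is_float_dtype(fmt[col]):
                fmt[col] = fmt[col].map(lambda v: f"{v:.2f}")
        header = "| " + " | ".join(fmt.columns) + " |"
        sep = "|" + "|".join(["---"] * len(fmt.columns)) + "|"
        lines.extend([header, sep])
        lines.extend("| " + " | ".join(str(v) for v in row) + " |"
                     for row in fmt.itertuples(index=False))
    markdown = "\n".join(lines) + "\n"

    if path_prefix is not None:
        Path(str(path_prefix) + ".md").write_text(markdown)
        Path(str(path_prefix) + ".csv").write_text(csv_text)
    return markdown, csv_text
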