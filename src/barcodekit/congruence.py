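"""Morphospecies vs MOTU congruence codes and their summaries.

Each morphospecies receives exactly one code per delimitation method:

* ``OK``  -- congruent: all its specimens form one MOTU shared with no other
  morphospecies;
* ``S``   -- split: its specimens are spread over two or more MOTUs;
* ``L``   -- lumped: some MOTU holding its specimens also holds specimens of
  another morphospecies;
* ``S+L`` -- both at once;
* ``NA``  -- the morphospecies has no sequence data for this marker.

The unit of accounting is the morphospecies (one code per species per
method), and summary percentages are computed over non-NA species only.
"""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .errors import DegenerateInputError, ParameterError
from .io import MotuPartition

CODES = ("OK", "S", "L", "S+L", "NA")


def classify_species(
    morpho: Mapping[str, str],
    part: MotuPartition,
    species: Iterable[str] | None = None,
) -> dict[str, str]:
    """One congruence code per morphospecies against a MOTU partition.

    *morpho* maps every specimen in *part* to its morphospecies label.
    *species* optionally extends the species universe; species without any
    specimen in the partition are coded ``NA``.
    """
    unlabeled = sorted(set(part.assignments) - set(morpho))
    if unlabeled:
        raise ParameterError(f"specimens without a morphospecies label: {unlabeled}")
    by_species: dict[str, set[str]] = {}
    motu_species: dict[str, set[str]] = {}
    for sp, motu in part.assignments.items():
        label = morpho[sp]
        by_species.setdefault(label, set()).add(motu)
        motu_species.setdefault(motu, set()).add(label)
    codes: dict[str, str] = {}
    universe = set(by_species)
    if species is not None:
        universe |= set(species)
    for label in universe:
        if label not in by_species:
            codes[label] = "NA"
            continue
        motus = by_species[label]
        split = len(motus) >= 2
        lump = any(len(motu_species[m]) >= 2 for m in motus)
        codes[label] = {
            (False, False): "OK",
            (True, False): "S",
            (False, True): "L",
            (True, True): "S+L",
        }[(split, lump)]
    return codes


def _round1(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _round0(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def summarize(
    columns: Mapping[str, tuple[Mapping[str, str], int]],
    mean_row: bool = True,
) -> pd.DataFrame:
    """Per-method congruence summary plus an across-method mean row.

    *columns* maps a method name to ``(codes, n_motus)`` where *codes* is the
    per-species code mapping (possibly containing NA).  Percentages are
    computed over non-NA species, rounded half-up to one decimal for display;
    the raw fractions are retained in ``frac_*`` columns.  The mean row is
    the arithmetic mean of the method columns (computed on raw fractions).
    """
    if not columns:
        raise DegenerateInputError("no code columns to summarise")
    rows = []
    for method, (codes, n_motus) in columns.items():
        counted = {c: 0 for c in CODES}
        for code in codes.values():
            if code not in counted:
                raise ParameterError(f"unknown congruence code {code!r}")
            counted[code] += 1
        n = sum(v for c, v in counted.items() if c != "NA")
        if n == 0:
            raise DegenerateInputError(f"method {method!r} has no non-NA species")
        fracs = {c: counted[c] / n for c in ("OK", "L", "S", "S+L")}
        rows.append(
            {
                "method": method,
                "n_species": n,
                "n_motus": int(n_motus),
                "pct_congruent": _round1(100 * fracs["OK"]),
                "pct_lump": _round1(100 * fracs["L"]),
                "pct_split": _round1(100 * fracs["S"]),
                "pct_lump_split": _round1(100 * fracs["S+L"]),
                "frac_congruent": fracs["OK"],
                "frac_lump": fracs["L"],
                "frac_split": fracs["S"],
                "frac_lump_split": fracs["S+L"],
            }
        )
    df = pd.DataFrame(rows).set_index("method")
    if mean_row and len(df) > 1:
        mean = {
            "n_species": _round0(df["n_species"].mean()),
            "n_motus": _round0(df["n_motus"].mean()),
        }
        for key in ("congruent", "lump", "split", "lump_split"):
            raw = df[f"frac_{key}"].mean()
            mean[f"pct_{key}"] = _round1(100 * raw)
            mean[f"frac_{key}"] = raw
        df.loc["Mean"] = mean
    return df


def consensus_classification(
    codes_by_method: Mapping[str, Mapping[str, str]]
) -> pd.DataFrame:
    """Majority-rule consensus over methods, per species.

    A species is flagged ``split`` when at least half of its non-NA method
    codes are S or S+L, ``lumped`` when at least half are L or S+L, ``both``
    when both hold, and ``congruent`` otherwise.
    """
    if len(codes_by_method) < 2:
        raise ParameterError("consensus needs at least 2 methods")
    species: set[str] = set()
    for codes in codes_by_method.values():
        species |= set(codes)
    rows = []
    for label in sorted(species):
        cell = [codes.get(label, "NA") for codes in codes_by_method.values()]
        non_na = [c for c in cell if c != "NA"]
        m = len(non_na)
        if m == 0:
            rows.append({"species": label, "consensus": "NA", "n_methods": 0})
            continue
        n_split = sum(c in ("S", "S+L") for c in non_na)
        n_lump = sum(c in ("L", "S+L") for c in non_na)
        split = n_split >= m / 2
        lump = n_lump >= m / 2
        consensus = (
            "both" if (split and lump) else "split" if split else "lumped" if lump else "congruent"
        )
        rows.append({"species": label, "consensus": consensus, "n_methods": m})
    return pd.DataFrame(rows).set_index("species")


# ---------------------------------------------------------------------------
# Packaged reference tables (Ponto-Caspian amphipod barcode survey)
# ---------------------------------------------------------------------------


def load_reference_codes() -> pd.DataFrame:
    """Published per-species congruence codes for the Ponto-Caspian amphipod
    barcode library: one row per morphospecies, one column per
    marker/method combination (values OK, S, L, S+L or NA)."""
    with resources.files("barcodekit.data").joinpath(
        "pontocaspian_congruence_codes.tsv"
    ).open() as fh:
        # keep_default_na: "NA" is a congruence code, not missing data
        return pd.read_csv(fh, sep="\t", keep_default_na=False).set_index("species")


def load_reference_motu_counts() -> dict[str, dict[str, int]]:
    """Published MOTU counts per marker and delimitation method."""
    with resources.files("barcodekit.data").joinpath(
        "pontocaspian_motu_counts.json"
    ).open() as fh:
        return json.load(fh)


def reference_summary(marker: str) -> pd.DataFrame:
    """Congruence summary recomputed from the packaged per-species codes."""
    table = load_reference_codes()
    counts = load_reference_motu_counts()[marker]
    prefix = {"COI": "coi_", "16S": "s16_"}[marker]
    columns = {}
    for method, n_motus in counts.items():
        col = prefix + method.lower().replace("=", "").replace(" ", "")
        codes = dict(table[col])
        columns[method] = (codes, n_motus)
    return summarize(columns)
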