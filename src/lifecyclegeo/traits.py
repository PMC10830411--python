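"""Species-level life-cycle and growth-form consensus from raw trait entries.

Multi-source plant trait databases record one free-text term per entry
(e.g. ``annual``, ``forb/herb``, ``tree``, ``10 years``). Building a usable
species database takes three steps:

1. :func:`resolve_names` maps raw names to accepted names through an exact
   synonym table (a pluggable stand-in for a full taxonomic name-resolution
   service); unmatched names are dropped and counted.
2. :func:`interpret_terms` annotates every entry with its life-cycle vote
   (annual / perennial / none / conflict) and growth-form vote
   (woody / herbaceous / none / conflict) through a versioned lexicon.
3. :func:`build_consensus` keeps only species whose votes are unanimous on
   each axis, drops crop species (their occurrences need not reflect natural
   habitat), and enforces the biological constraint that woody plants are
   perennial.

All functions take and return pandas DataFrames; entry tables have columns
``raw_name``, ``raw_term`` and optionally ``source``.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

LIFE_CYCLES = ("annual", "perennial", "none", "conflict")
GROWTH_FORMS = ("woody", "herbaceous", "none", "conflict")


def default_lexicon() -> pd.DataFrame:
    """The term-interpretation lexicon shipped with the package.

    Columns: raw_term, life_cycle, growth_form. Terms are matched
    case-insensitively after whitespace stripping. Terms absent from the
    lexicon contribute no vote on either axis.
    """
    with resources.files("lifecyclegeo.data").joinpath("term_lexicon.csv").open() as fh:
        lex = pd.read_csv(fh)
    return lex


def resolve_names(
    entries: pd.DataFrame, synonyms: Mapping[str, str] | pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Map raw names to accepted names; drop names absent from the table.

    ``synonyms`` maps raw name -> accepted name and must include identity
    rows for names already accepted (exact lookup; no fuzzy matching).

    Returns ``(resolved, n_dropped)`` where ``resolved`` carries an
    ``accepted_name`` column.
    """
    if isinstance(synonyms, pd.DataFrame):
        if synonyms["raw_name"].duplicated().any():
            raise ValueError("synonym table keys must be unique")
        mapping = dict(zip(synonyms["raw_name"], synonyms["accepted_name"]))
    else:
        mapping = dict(synonyms)
    out = entries.copy()
    out["accepted_name"] = out["raw_name"].map(mapping)
    n_dropped = int(out["accepted_name"].isna().sum())
    out = out.dropna(subset=["accepted_name"]).reset_index(drop=True)
    return out, n_dropped


def interpret_terms(entries: pd.DataFrame, lexicon: pd.DataFrame | None = None) -> pd.DataFrame:
    """Annotate entries with (life_cycle, growth_form) votes from the lexicon.

    A term not covered by the lexicon defaults to no vote on either axis
    ("none"/"none"); a term the lexicon marks ``conflict`` on an axis
    contributes no vote there either, but flags that its information was
    self-contradictory.
    """
    lex = default_lexicon() if lexicon is None else lexicon
    bad_lc = set(lex["life_cycle"]) - set(LIFE_CYCLES)
    bad_gf = set(lex["growth_form"]) - set(GROWTH_FORMS)
    if bad_lc or bad_gf:
        raise ValueError(f"lexicon contains unknown categories: {bad_lc | bad_gf}")
    key = lex["raw_term"].str.strip().str.lower()
    lc_map = dict(zip(key, lex["life_cycle"]))
    gf_map = dict(zip(key, lex["growth_form"]))
    out = entries.copy()
    term = out["raw_term"].astype(str).str.strip().str.lower()
    out["life_cycle"] = term.map(lc_map).fillna("none")
    out["growth_form"] = term.map(gf_map).fillna("none")
    return out


def _axis_consensus(votes: pd.Series, categories: tuple[str, str]) -> str:
    """Unanimity rule for one axis: 'none' if no votes, the unanimous
    category, or 'conflict' on any disagreement."""
    real = votes[votes.isin(categories)]
    if real.empty:
        return "none"
    uniq = real.unique()
    return uniq[0] if len(uniq) == 1 else "conflict"


def build_consensus(
    annotated: pd.DataFrame, crop_list: Iterable[str] = ()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-species consensus traits under the unanimity rule.

    A species is kept iff its life-cycle votes are unanimous (at least one
    vote), its growth-form votes are unanimous or absent (absent yields
    growth form ``unknown``), it is internally consistent (a woody consensus
    with an annual life cycle is impossible and excludes the species), and
    it is not a crop.

    Returns ``(species, report)``: a DataFrame with columns accepted_name,
    life_cycle (annual/perennial), growth_form (woody/herbaceous/unknown),
    n_entries; and a tally partitioning every input species into exactly one
    of kept / excluded_conflict / excluded_crop / excluded_no_lifecycle.
    """
    crops = set(crop_list)
    kept_rows: list[dict] = []
    report = {"kept": 0, "excluded_conflict": 0, "excluded_crop": 0, "excluded_no_lifecycle": 0}

    for name, grp in annotated.groupby("accepted_name", sort=True):
        lc = _axis_consensus(grp["life_cycle"], ("annual", "perennial"))
        gf = _axis_consensus(grp["growth_form"], ("woody", "herbaceous"))
        if lc == "conflict" or gf == "conflict":
            report["excluded_conflict"] += 1
            continue
        if lc == "none":
            report["excluded_no_lifecycle"] += 1
            continue
        if gf == "woody" and lc == "annual":
            # woody implies perennial; cross-axis inconsistency
            report["excluded_conflict"] += 1
            continue
        if name in crops:
            report["excluded_crop"] += 1
            continue
        kept_rows.append(
            {
                "accepted_name": name,
                "life_cycle": lc,
                "growth_form": gf if gf != "none" else "unknown",
                "n_entries": len(grp),
            }
        )
        report["kept"] += 1

    species = pd.DataFrame(kept_rows, columns=["accepted_name", "life_cycle", "growth_form", "n_entries"])
    return species, report


def build_species_traits(
    entries: pd.DataFrame,
    synonyms: Mapping[str, str] | pd.DataFrame,
    crop_list: Iterable[str] = (),
    lexicon: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Full pipeline: resolve names, interpret terms, build consensus."""
    resolved, n_dropped = resolve_names(entries, synonyms)
    annotated = interpret_terms(resolved, lexicon)
    species, report = build_consensus(annotated, crop_list)
    report["names_dropped"] = n_dropped
    return species, report
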