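"""Table-driven resolution of study identifiers to KEGG IDs.

All lookups are pure functions of (keys, table): external services (name
converters, KEGG REST search) are reduced to offline tables prepared once,
because metabolite naming drifts and silent online re-resolution would make
results irreproducible.  Matching is conservative — normalization only, no
fuzzy matching — so an unmatched key is reported rather than guessed.

The proxy mechanism covers measured metabolites that have no KEGG entry but a
close chemical counterpart that does (the classic case: acylcarnitines
proxied by their acyl-CoA); every substitution is logged and flagged so
downstream reports can mark proxied metabolites.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pandas as pd

__all__ = [
    "normalize_key",
    "load_mapping_table",
    "resolve_ids",
    "apply_proxy",
    "GENE",
    "METABOLITE",
    "PROXY",
]

logger = logging.getLogger(__name__)

GENE = "gene"
METABOLITE = "metabolite"
PROXY = "proxy"

_WS = re.compile(r"\s+")
_DASHES = re.compile(r"[‐-―−]")  # unicode hyphen/dash variants
_KEGG_COMPOUND = re.compile(r"^C\d{5}$")
_KEGG_GENE = re.compile(r"^hsa:\d+$")


def normalize_key(key: str) -> str:
    """Conservative name normalization: case, whitespace, dash variants.

    Lowercases, collapses runs of whitespace, folds unicode dashes to '-',
    and removes spaces around hyphens ('L - proline' == 'l-proline').  No
    fuzzy matching beyond this.
    """
    s = _DASHES.sub("-", key.strip().lower())
    s = _WS.sub(" ", s)
    s = re.sub(r"\s*-\s*", "-", s)
    return s


def load_mapping_table(path: str | Path) -> pd.DataFrame:
    """Read a 3-column mapping table: source_key, kegg_id, mapping_kind.

    Tab-delimited, '#' comments, no header.  Source keys are normalized on
    load; duplicate keys within a mapping kind are an error.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["source_key", "kegg_id", "mapping_kind"],
        dtype=str,
    )
    df["source_key"] = df["source_key"].map(normalize_key)
    dup = df[df.duplicated(["source_key", "mapping_kind"], keep=False)]
    if not dup.empty:
        raise ValueError(
            f"duplicate source keys within a mapping kind: {sorted(set(dup['source_key']))}"
        )
    return df


def _lookup(table: pd.DataFrame, kind: str) -> dict[str, str]:
    sub = table[table["mapping_kind"] == kind]
    return dict(zip(sub["source_key"], sub["kegg_id"]))


def resolve_ids(
    keys: list[str],
    table: pd.DataFrame,
    kind: str,
    accept_kegg_ids: bool = False,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Split ``keys`` into resolved (key, kegg_id) pairs and unresolved keys.

    Every input key lands in exactly one output list; input multiplicity is
    preserved.  With ``accept_kegg_ids`` keys that already look like KEGG IDs
    (``C#####`` compounds, ``hsa:#`` genes) resolve to themselves.  The mapped
    proportion is logged — disclosure of how much of a study maps is part of
    the result.
    """
    mapping = _lookup(table, kind)
    pattern = _KEGG_GENE if kind == GENE else _KEGG_COMPOUND
    resolved: list[tuple[str, str]] = []
    unresolved: list[str] = []
    for key in keys:
        norm = normalize_key(key)
        if norm in mapping:
            resolved.append((key, mapping[norm]))
        elif accept_kegg_ids and pattern.match(key.strip()):
            resolved.append((key, key.strip()))
        else:
            unresolved.append(key)
    if keys:
        logger.info(
            "resolve_ids(%s): %d/%d resolved (%.0f%%)",
            kind,
            len(resolved),
            len(keys),
            100 * len(resolved) / len(keys),
        )
    return resolved, unresolved


def apply_proxy(
    metabolite_keys: list[str], table: pd.DataFrame
) -> tuple[list[str], list[tuple[str, str]]]:
    """Substitute proxy KEGG IDs for metabolites lacking a direct mapping.

    For each key: a direct metabolite mapping always wins (no substitution);
    otherwise, if a proxy row exists, the key is replaced by the proxy's KEGG
    ID and the substitution ``(original_key, kegg_id)`` is logged.  Keys with
    neither pass through unchanged.  Idempotent: substituted KEGG IDs have no
    proxy rows, so a second application is the identity.
    """
    direct = _lookup(table, METABOLITE)
    proxies = _lookup(table, PROXY)
    out: list[str] = []
    log: list[tuple[str, str]] = []
    for key in metabolite_keys:
        norm = normalize_key(key)
        if norm not in direct and norm in proxies:
            out.append(proxies[norm])
            log.append((key, proxies[norm]))
        else:
            out.append(key)
    for original, kegg_id in log:
        logger.info("apply_proxy: %r -> %s", original, kegg_id)
    return out, log
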