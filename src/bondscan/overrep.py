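"""Per-term Fisher-exact over-representation of GO annotations.

The universe is restricted to background proteins that carry at least one
annotation (matching the convention of the enrichment-tool family this
mirrors). Each term gets a one-sided (greater) Fisher exact test; p-values
are reported unadjusted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

_GO_ID = re.compile(r"^GO:\d{7}$")


class AnnotationError(Exception):
    """Malformed annotation input."""


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    term_name: str
    n_background: int
    n_selected: int
    n_expected: float
    p_value: float

    def as_row(self) -> dict:
        return {
            "term_id": self.term_id,
            "term_name": self.term_name,
            "n_background": self.n_background,
            "n_selected": self.n_selected,
            "n_expected": self.n_expected,
            "p_value": self.p_value,
        }


def load_annotations(
    path: str | Path,
) -> tuple[dict[str, frozenset[str]], dict[str, str]]:
    """Read a protein -> GO-term multimap from a 2- or 3-column TSV.

    Columns: protein_id, GO ID (``GO:`` + 7 digits), optional term name.
    Duplicate (protein, term) pairs collapse. Returns (multimap, term names).
    """
    path = Path(path)
    mapping: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    n_lines = 0
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise AnnotationError(f"{path}:{lineno}: expected >= 2 columns")
        protein_id, term_id = parts[0].strip(), parts[1].strip()
        if not _GO_ID.match(term_id):
            raise AnnotationError(
                f"{path}:{lineno}: malformed GO ID {term_id!r}")
        mapping.setdefault(protein_id, set()).add(term_id)
        if len(parts) >= 3 and parts[2].strip():
            names[term_id] = parts[2].strip()
        n_lines += 1
    if n_lines == 0:
        raise AnnotationError(f"{path}: no annotation lines")
    return {p: frozenset(t) for p, t in mapping.items()}, names


def enrich(
    selected: Iterable[str],
    background: Iterable[str],
    annotations: Mapping[str, frozenset[str] | set[str]],
    term_names: Mapping[str, str] | None = None,
) -> list[EnrichmentRow]:
    """One-sided Fisher exact over-representation per term.

    ``selected`` must be a subset of ``background``. Background proteins with
    no annotation are excluded from the universe (and logged). Rows are
    sorted by ascending p then term id.
    """
    selected = set(selected)
    background = set(background)
    if not selected <= background:
        extra = sorted(selected - background)[:5]
        raise ValueError(f"selected proteins missing from background: {extra}")
    if not annotations:
        raise ValueError("annotation map is empty")

    universe = {p for p in background if annotations.get(p)}
    dropped = len(background) - len(universe)
    if dropped:
        logger.info("excluded %d unannotated background proteins from universe",
                    dropped)
    sel_u = selected & universe
    n_universe = len(universe)
    n_sel = len(sel_u)
    if n_universe == 0:
        raise ValueError("no annotated proteins in background")

    term_members: dict[str, set[str]] = {}
    for protein in universe:
        for term in annotations[protein]:
            term_members.setdefault(term, set()).add(protein)

    term_names = term_names or {}
    rows = []
    for term, members in term_members.items():
        k_bg = len(members)
        k_sel = len(members & sel_u)
        # P(X >= k_sel), X ~ Hypergeom(N=n_universe, K=k_bg, n=n_sel)
        p = float(hypergeom.sf(k_sel - 1, n_universe, k_bg, n_sel))
        rows.append(EnrichmentRow(
            term_id=term,
            term_name=term_names.get(term, ""),
            n_background=k_bg,
            n_selected=k_sel,
            n_expected=k_bg * n_sel / n_universe,
            p_value=min(1.0, p),
        ))
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return rows
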