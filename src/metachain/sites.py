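"""Anatomical site taxonomy.

The model runs on a fixed, closed set of anatomical states: the breast
primary, eight metastatic locations, and an absorbing ``deceased`` state.
Any input label outside the taxonomy is coerced to ``other`` with a
logged warning so that cohort files from heterogeneous registries still
load.
"""

from __future__ import annotations

import logging

logger = logging.getLogger(__name__)

BREAST = "breast"
DECEASED = "deceased"

#: Canonical ordered taxonomy. ``breast`` is the unique origin state and
#: ``deceased`` the unique absorbing terminal state.
TAXONOMY: tuple[str, ...] = (
    BREAST,
    "bone",
    "chest_wall",
    "ln_mammary",
    "ln_distant",
    "lung_pleura",
    "liver",
    "brain",
    "other",
    DECEASED,
)

#: Sites that can host a metastatic tumour (everything but origin/absorbing).
MET_SITES: tuple[str, ...] = tuple(
    s for s in TAXONOMY if s not in (BREAST, DECEASED)
)

_ALIASES = {
    "ln_mam": "ln_mammary",
    "ln (mam)": "ln_mammary",
    "ln_dist": "ln_distant",
    "ln (dist)": "ln_distant",
    "lung": "lung_pleura",
    "pleura": "lung_pleura",
    "lung/pleura": "lung_pleura",
    "chest wall": "chest_wall",
}


def canonical_site(label: str) -> str:
    """Map an input label onto the taxonomy.

    Known aliases are normalised; anything else collapses to ``other``
    with a warning, keeping the state space closed.
    """
    key = label.strip().lower()
    if key in TAXONOMY:
        return key
    if key in _ALIASES:
        return _ALIASES[key]
    logger.warning("unknown site label %r mapped to 'other'", label)
    return "other"


def site_index(site: str, taxonomy: tuple[str, ...] = TAXONOMY) -> int:
    return taxonomy.index(site)
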