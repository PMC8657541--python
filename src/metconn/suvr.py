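"""Reference-region normalization to standard uptake value ratios (SUVR).

Each subject's regional uptake is divided by that subject's reference
value — the unweighted mean of the uptake over all atlas regions flagged
``is_reference`` (by default, the bilateral medulla).  SUVR removes global
per-subject scaling (injected dose, body weight, scanner sensitivity): a
subject's SUVR row is invariant to multiplying its raw row by any positive
constant.

Pooling both medulla hemispheres rather than using a single mask keeps
each reference region's own SUVR variable across subjects, so reference
regions remain usable as network nodes (a sole reference region would have
identically 1.0 SUVR, zero variance, and undefined correlations).
"""

from __future__ import annotations

from typing import Iterable, Optional

from .errors import ConfigurationError, ValidationError
from .uptake import SUVRTable, UptakeTable


def compute_suvr(
    table: UptakeTable, reference: Optional[Iterable[str]] = None
) -> SUVRTable:
    """Normalize an uptake table by its per-subject reference mean.

    Parameters
    ----------
    table
        Raw uptake, strictly positive.
    reference
        Region names to pool as the reference, or None for the atlas
        default (all regions flagged ``is_reference``).

    Returns
    -------
    SUVRTable
        Same shape and ordering as the input; for each subject the mean
        SUVR over the reference regions is exactly 1.
    """
    atlas = table.atlas
    if reference is None:
        ref_names = atlas.reference_names
    else:
        ref_names = list(reference)
        if not ref_names:
            raise ConfigurationError("reference set must not be empty")
        missing = [n for n in ref_names if n not in atlas.names]
        if missing:
            raise ConfigurationError(f"reference regions not in atlas: {missing}")
    ref_idx = [atlas.index_of(n) for n in ref_names]
    ref_values = table.values[:, ref_idx].mean(axis=1)
    bad = ref_values <= 0
    if bad.any():
        sid = table.subject_ids[int(bad.argmax())]
        raise ValidationError(f"non-positive reference uptake for subject {sid!r}")
    suvr = table.values / ref_values[:, None]
    return SUVRTable(
        subject_ids=list(table.subject_ids),
        groups=list(table.groups),
        values=suvr,
        atlas=atlas,
        reference_definition={
            "regions": ref_names,
            "method": "unweighted_mean",
        },
    )
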