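"""Signed Kullback–Leibler quantification of preference contagion.

A participant's discounting preference in a block is summarized by the
KU distribution N(km, ku^2). The shift between a post-exposure self
block and the Self1 baseline is the KL divergence between those two
normals, in base-10 units (matching how the divergence is defined for
this analysis), signed positive when the shift is *toward* the exposed
other's rate and negative when it is away:

    sign = sign( (km_other - km_self1) / (km_after - km_self1) )

Both simulated others are constructed from the Self1 baseline, so both
exposures are anchored at Self1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

__all__ = ["DivergenceResult", "kl_normal_base10", "signed_dkl", "influence_table"]

#: |km_after - km_self1| below this is treated as "no shift" (sign 0).
SIGN_EPS = 1e-8


def kl_normal_base10(p_mean, p_sd, q_mean, q_sd):
    """KL(P || Q) between two normals, with the base-10 logarithm.

    Closed form: [ln(q_sd/p_sd) + (p_sd^2 + (p_mean-q_mean)^2)/(2 q_sd^2)
    - 1/2] / ln(10). Non-negative; zero iff P == Q. Broadcasts.
    """
    p_sd = np.asarray(p_sd, float)
    q_sd = np.asarray(q_sd, float)
    if np.any(p_sd <= 0) or np.any(q_sd <= 0):
        raise ValueError("standard deviations must be positive")
    p_mean = np.asarray(p_mean, float)
    q_mean = np.asarray(q_mean, float)
    nats = (
        np.log(q_sd / p_sd)
        + (p_sd**2 + (p_mean - q_mean) ** 2) / (2.0 * q_sd**2)
        - 0.5
    )
    out = nats / np.log(10.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DivergenceResult:
    """Signed divergence for one subject x one other-exposure."""

    d_kl: float
    sign: int
    signed_d_kl: float
    other_block: Optional[int] = None  # 2 or 4
    other_label: Optional[str] = None  # more_impulsive | more_patient
    km_self1: float = np.nan
    ku_self1: float = np.nan
    km_after: float = np.nan
    ku_after: float = np.nan
    km_other: float = np.nan


def signed_dkl(
    km_self1: float,
    ku_self1: float,
    km_after: float,
    ku_after: float,
    km_other: float,
    other_block: Optional[int] = None,
    other_label: Optional[str] = None,
) -> DivergenceResult:
    """Signed KL shift of the discounting distribution after an exposure.

    P is the post-exposure distribution N(km_after, ku_after^2), Q the
    Self1 baseline N(km_self1, ku_self1^2); the magnitude is KL(P || Q)
    in base-10 units. The sign follows the ratio rule above; when km did
    not move (|km_after - km_self1| < 1e-8) the sign is 0, with a warning.
    """
    d = kl_normal_base10(km_after, ku_after, km_self1, ku_self1)
    delta = km_after - km_self1
    if abs(delta) < SIGN_EPS:
        warnings.warn(
            "km unchanged between baseline and post-exposure block; "
            "signed divergence set to 0",
            stacklevel=2,
        )
        sign = 0
    else:
        sign = int(np.sign((km_other - km_self1) / delta))
    return DivergenceResult(
        d_kl=float(d),
        sign=sign,
        signed_d_kl=float(sign * d),
        other_block=other_block,
        other_label=other_label,
        km_self1=km_self1,
        ku_self1=ku_self1,
        km_after=km_after,
        ku_after=ku_after,
        km_other=km_other,
    )


#: Self block fitted after each other-exposure block.
AFTER_BLOCK: Dict[int, int] = {2: 3, 4: 5}


def influence_table(block_params: pd.DataFrame, others: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-exposure signed-divergence table.

    Parameters
    ----------
    block_params : tidy per-subject, per-block KU parameter estimates
        with columns ``subject_id, block, km, ku`` (optionally
        ``group``); must include blocks 1, and 3 and/or 5.
    others : one row per subject x other-exposure with columns
        ``subject_id, other_block (2 or 4), k_other``.

    Returns
    -------
    DataFrame with one row per subject x exposure: the divergence, the
    sign, the analysis label of the other (assigned relative to the
    fitted Self1 km, so it may disagree with the design intent), and a
    ``both_same_label`` flag marking subjects whose two others fall on
    the same side of their baseline — such subjects contribute rows only
    for that label, and their data is unavailable for the opposite one.
    """
    req = {"subject_id", "block", "km", "ku"}
    if not req.issubset(block_params.columns):
        raise ValueError(f"block_params needs columns {sorted(req)}")
    wide = block_params.set_index(["subject_id", "block"])
    group_col = (
        block_params.drop_duplicates("subject_id").set_index("subject_id")["group"]
        if "group" in block_params.columns
        else None
    )
    rows = []
    for subject, sub in others.groupby("subject_id", sort=False):
        try:
            base = wide.loc[(subject, 1)]
        except KeyError:
            raise ValueError(f"subject {subject!r} has no Self1 (block 1) fit")
        labels = {
            int(r.other_block): (
                "more_impulsive" if r.k_other >= base["km"] else "more_patient"
            )
            for r in sub.itertuples()
        }
        both_same = len(set(labels.values())) == 1 and len(labels) == 2
        for r in sub.itertuples():
            blk = int(r.other_block)
            if blk not in AFTER_BLOCK:
                raise ValueError("other_block must be 2 or 4")
            after = wide.loc[(subject, AFTER_BLOCK[blk])]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = signed_dkl(
                    km_self1=float(base["km"]),
                    ku_self1=float(base["ku"]),
                    km_after=float(after["km"]),
                    ku_after=float(after["ku"]),
                    km_other=float(r.k_other),
                    other_block=blk,
                    other_label=labels[blk],
                )
            rows.append(
                {
                    "subject_id": subject,
                    "group": group_col.get(subject) if group_col is not None else None,
                    "other_block": blk,
                    "other_label": res.other_label,
                    "km_other": res.km_other,
                    "km_self1": res.km_self1,
                    "ku_self1": res.ku_self1,
                    "km_after": res.km_after,
                    "ku_after": res.ku_after,
                    "d_kl": res.d_kl,
                    "sign": res.sign,
                    "signed_d_kl": res.signed_d_kl,
                    "both_same_label": both_same,
                }
            )
    return pd.DataFrame(rows)
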