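"""Lateralization index of hemispheric activation.

For a homologous region pair the lateralization index is

    LI = (ΣWA_C − ΣWA_I) / (ΣWA_C + ΣWA_I)

where ΣWA_C and ΣWA_I are the summed channel wavelet amplitudes of the
contralesional and ipsilesional members.  LI ranges from +1 (activation
confined to the contralesional hemisphere) to −1 (ipsilesional only);
0 means balanced activation.  When both sums are zero the index is
undefined and is reported as missing rather than silently set to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import DomainError
from .montage_io import REGIONS


class UndefinedLIError(DomainError):
    """Both hemispheric activation sums are zero; LI is undefined."""


def lateralization_index(wa_c_sum: float, wa_i_sum: float) -> float:
    """LI = (C − I)/(C + I) for non-negative activation sums."""
    if wa_c_sum < 0 or wa_i_sum < 0:
        raise DomainError("activation sums must be non-negative")
    total = wa_c_sum + wa_i_sum
    if total == 0:
        raise UndefinedLIError("both hemispheric WA sums are zero")
    return (wa_c_sum - wa_i_sum) / total


@dataclass(frozen=True)
class LIRow:
    region: str
    li: float | None      # None when undefined (both sums zero)
    wa_c_sum: float
    wa_i_sum: float


def region_li(region_wa_sums: Mapping[str, float]) -> list[LIRow]:
    """LI for each of the seven homologous region pairs.

    ``region_wa_sums`` maps effective region labels (``ISFC``, ``CSFC``,
    ...) to summed WA values, e.g. the output of
    :func:`nirswave.wavelet_amplitude.region_wa` with ``aggregator='sum'``.
    """
    rows: list[LIRow] = []
    for region in REGIONS:
        try:
            c = float(region_wa_sums["C" + region])
            i = float(region_wa_sums["I" + region])
        except KeyError as exc:
            raise DomainError(f"missing hemispheric WA sum for {exc}") from exc
        try:
            li: float | None = lateralization_index(c, i)
        except UndefinedLIError:
            li = None
        rows.append(LIRow(region=region, li=li, wa_c_sum=c, wa_i_sum=i))
    return rows
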