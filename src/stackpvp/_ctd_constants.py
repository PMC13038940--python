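"""Pinned three-group physicochemical partitions for the CTD descriptors.

Thirteen properties, each partitioning the 20-letter alphabet into three
disjoint groups, following the iFeature convention (seven hydrophobicity
scales, normalized van der Waals volume, polarity, polarizability,
charge, secondary-structure propensity, solvent accessibility).  This is
the only partition set consistent with CTD block dimensions 39/39/195.

Do not edit: descriptor values are only comparable across runs when
these tables are stable.
"""

from __future__ import annotations

#: property -> (group1, group2, group3); each triple partitions the alphabet.
CTD_GROUPS: dict[str, tuple[str, str, str]] = {
    "hydrophobicity_PRAM900101": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "hydrophobicity_ARGP820101": ("QSTNGDE", "RAHCKMV", "LYPFIW"),
    "hydrophobicity_ZIMJ680101": ("QNGSWTDERA", "HMCKV", "LPFYI"),
    "hydrophobicity_PONP930101": ("KPDESNQT", "GRHA", "YMFWLCVI"),
    "hydrophobicity_CASG920101": ("KDEQPSRNTG", "AHYMLV", "FIWC"),
    "hydrophobicity_ENGD860101": ("RDKENQHYP", "SGTAW", "CVLIMF"),
    "hydrophobicity_FASG890101": ("KERSQD", "NTPG", "AYHWVMFLIC"),
    "normwaalsvolume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondarystruct": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solventaccess": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}

CTD_PROPERTIES: tuple[str, ...] = tuple(CTD_GROUPS)

#: Five-group amino-acid classes for GAAC / GDPC (iFeature convention).
GAAC_GROUPS: dict[str, str] = {
    "aliphatic": "GAVLMI",
    "aromatic": "FYW",
    "positive": "KRH",
    "negative": "DE",
    "uncharged": "STCPNQ",
}
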