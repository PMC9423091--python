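"""Published variance components and derived genetic parameters of the
conifer polycross breeding study, used as fixed inputs and expected values.

``COMPONENTS`` holds the per-model variance components (additive,
site-by-additive, dominance, site-by-dominance, mean residual) for the
eight traits; ``H2_NARROW``, ``RB_PUBLISHED`` and ``H2_BROAD`` hold the published heritability and type-B
correlation values derived from them.  Components of the growth and
foliar traits are printed as integers, those of the wood traits at two
decimals — interval checks must propagate that input precision.
"""

TRAITS = ["HT", "DBH", "F.AT", "F.TM", "W.AT", "W.TT", "W.TL", "W.TE"]

COMPONENTS = {
    "ABLUP-PX": {
        "a": [2002, 64, 14826426, 30657455, 0.23, 0.15, 0.13, 0.14],
        "sa": [640, 14, 4015174, 12452425, 0, 0, 0, 0],
        "e": [9057, 578, 26876824, 75372139, 0.54, 0.51, 0.66, 0.35],
    },
    "ABLUP-FS-A": {
        "a": [1556, 51, 15533815, 37118801, 0.12, 0.09, 0.12, 0.09],
        "sa": [705, 49, 1689946, 4366040, 0.04, 0.03, 0, 0.03],
        "e": [9341, 550, 29077111, 78932462, 0.62, 0.55, 0.68, 0.38],
    },
    "GBLUP-A": {
        "a": [1468, 58, 11737942, 27454351, 0.14, 0.12, 0.11, 0.10],
        "sa": [824, 56, 2930377, 7717227, 0.06, 0.05, 0, 0.04],
        "e": [8753, 511, 27662309, 75605758, 0.54, 0.47, 0.67, 0.33],
    },
    "ABLUP-FS-AD": {
        "a": [1452, 50, 15533579, 37123981, 0.11, 0.08, 0.11, 0.08],
        "sa": [721, 47, 1689637, 4361816, 0.04, 0.03, 0, 0.03],
        "d": [1076, 0, 18, 51, 0.12, 0.11, 0.05, 0.06],
        "sd": [53, 34, 36, 15, 0, 0, 0, 0],
        "e": [8274, 517, 29077853, 78933337, 0.50, 0.45, 0.64, 0.32],
    },
    "GBLUP-AD": {
        "a": [1158, 42, 11737609, 27414139, 0.14, 0.11, 0.10, 0.09],
        "sa": [694, 56, 2929279, 7720452, 0.06, 0.06, 0, 0.04],
        "d": [1049, 81, 8, 22, 0.04, 0.06, 0.13, 0.04],
        "sd": [1685, 17, 4, 56, 0, 0, 0, 0],
        "e": [6044, 417, 27663310, 75623294, 0.49, 0.41, 0.54, 0.30],
    },
}

H2_NARROW = {
    "ABLUP-PX": [.17, .10, .32, .26, .29, .23, .17, .28],
    "ABLUP-FS-A": [.13, .08, .34, .31, .15, .13, .15, .17],
    "ABLUP-FS-AD": [.13, .08, .34, .31, .14, .12, .14, .16],
    "GBLUP-A": [.13, .09, .28, .25, .19, .18, .14, .20],
    "GBLUP-AD": [.11, .07, .28, .25, .19, .18, .13, .19],
}

RB_PUBLISHED = {
    "ABLUP-PX": [.76, .82, .79, .71, 1, 1, 1, 1],
    "ABLUP-FS-A": [.69, .51, .9, .89, .77, .76, 1, .77],
    "ABLUP-FS-AD": [.67, .52, .9, .89, .75, .74, 1, .76],
    "GBLUP-A": [.64, .51, .8, .78, .71, .68, 1, .69],
    "GBLUP-AD": [.63, .43, .8, .78, .71, .67, 1, .68],
}

H2_BROAD = {
    "ABLUP-FS-AD": [.22, .08, .34, .31, .30, .28, .20, .29],
    "GBLUP-AD": [.21, .20, .28, .25, .25, .27, .29, .28],
}


def half_ulp(value: float) -> float:
    """Half of the printed precision: integers above 10, 2 dp below."""
    return 0.5 if value >= 10 else 0.005
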