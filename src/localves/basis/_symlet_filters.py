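"""Scaling (low-pass) filter coefficients of the least-asymmetric
Daubechies wavelets (symlets) SymN, N = 4..12.

These are the published symlet coefficient tables, normalized so that
sum(h) = sqrt(2).  The wavelet (high-pass) filter follows from the
quadrature-mirror relation g_k = (-1)^k h_{2N-1-k} and is generated in
code, not stored.  Verified at import time against the admissibility and
double-shift orthogonality invariants (see wavelets.py).
"""

SYMLET_SCALING_FILTERS = {
    4: [
        0.0322231006040427,
        -0.012603967262037833,
        -0.09921954357684722,
        0.29785779560527736,
        0.8037387518059161,
        0.49761866763201545,
        -0.02963552764599851,
        -0.07576571478927333,
    ],
    5: [
        0.019538882735286728,
        -0.021101834024758855,
        -0.17532808990845047,
        0.01660210576452232,
        0.6339789634582119,
        0.7234076904024206,
        0.1993975339773936,
        -0.039134249302383094,
        0.029519490925774643,
        0.027333068345077982,
    ],
    6: [
        -0.007800708325034148,
        0.0017677118642428036,
        0.04472490177066578,
        -0.021060292512300564,
        -0.07263752278646252,
        0.3379294217276218,
        0.787641141030194,
        0.4910559419267466,
        -0.048311742585633,
        -0.11799011114819057,
        0.0034907120842174702,
        0.015404109327027373,
    ],
    7: [
        0.010268176708511255,
        0.004010244871533663,
        -0.10780823770381774,
        -0.14004724044296152,
        0.2886296317515146,
        0.767764317003164,
        0.5361019170917628,
        0.017441255086855827,
        -0.049552834937127255,
        0.0678926935013727,
        0.03051551316596357,
        -0.01263630340325193,
        -0.0010473848886829163,
        0.002681814568257878,
    ],
    8: [
        0.0018899503327594609,
        -0.0003029205147213668,
        -0.01495225833704823,
        0.003808752013890615,
        0.049137179673607506,
        -0.027219029917056003,
        -0.05194583810770904,
        0.3644418948353314,
        0.7771857517005235,
        0.4813596512583722,
        -0.061273359067658524,
        -0.1432942383508097,
        0.007607487324917605,
        0.03169508781149298,
        -0.0005421323317911481,
        -0.0033824159510061256,
    ],
    9: [
        0.0010694900329086053,
        -0.0004731544986800831,
        -0.010264064027633142,
        0.008859267493400484,
        0.06207778930288603,
        -0.018233770779395985,
        -0.19155083129728512,
        0.035272488035271894,
        0.6173384491409358,
        0.717897082764412,
        0.238760914607303,
        -0.05456895843083407,
        0.0005834627461258068,
        0.03022487885827568,
        -0.01152821020767923,
        -0.013271967781817119,
        0.0006197808889855868,
        0.0014009155259146807,
    ],
    10: [
        -0.0004593294210046588,
        5.7036083618494284e-05,
        0.004593173585311828,
        -0.0008043589320165449,
        -0.02035493981231129,
        0.005764912033581909,
        0.04999497207737669,
        -0.0319900568824278,
        -0.03553674047381755,
        0.38382676106708546,
        0.7695100370211071,
        0.47169066693843925,
        -0.07088053578324385,
        -0.15949427888491757,
        0.011609893903711381,
        0.0459272392310922,
        -0.0014653825813050513,
        -0.008641299277022422,
        9.563267072289475e-05,
        0.0007701598091144901,
    ],
    11: [
        0.0004892636102619239,
        0.00011053509764272153,
        -0.006389603666454892,
        -0.0020034719001093887,
        0.04300019068155228,
        0.03526675956446655,
        -0.1446023437053156,
        -0.2046547944958006,
        0.23768990904924897,
        0.7303435490883957,
        0.5720229780100871,
        0.09719839445890947,
        -0.022832651022562687,
        0.06997679961073414,
        0.0370374159788594,
        -0.024080841595864003,
        -0.009857934828789794,
        0.00651249567477145,
        0.0005883527353969915,
        -0.0017343662672978692,
        -3.8795655736158566e-05,
        0.00017172195069934854,
    ],
    12: [
        -0.0001790665869750869,
        -1.8158078862617515e-05,
        0.002350297614183465,
        0.00030764779631059454,
        -0.014589836449234145,
        -0.0026043910313322326,
        0.05780417944550566,
        0.01530174062247884,
        -0.17037069723886492,
        -0.07833262231634322,
        0.46274103121927235,
        0.7634790977836572,
        0.39888597239022,
        -0.022162306170337816,
        -0.03584883073695439,
        0.04917931829966084,
        0.0075537806116804775,
        -0.024220722675013445,
        -0.0014089092443297553,
        0.007414965517654251,
        0.00018021409008538188,
        -0.0013497557555715387,
        -1.1353928041541452e-05,
        0.00011196719424656033,
    ],
}
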