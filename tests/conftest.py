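import numpy as np
import pytest

import facegrid as fg


@pytest.fixture(scope="session")
def blob_spec():
    return fg.FixtureSpec(seed=0)


@pytest.fixture(scope="session")
def blob(blob_spec):
    return fg.make_blob_protein(blob_spec)


@pytest.fixture(scope="session")
def charged_pair():
    """Contact pair with engineered +1/-1 charges and the planted residue sets."""
    a, b = fg.make_contact_pair(fg.FixtureSpec(seed=0))
    return fg.engineer_charge_interface(a, b)


@pytest.fixture(scope="session")
def charge_prediction(charged_pair):
    a, b, _, _ = charged_pair
    return fg.predict_interface(a, b, "charge", fg.Config(rng_seed=0))


def planted_face_pair(prediction, struct_a, struct_b, patch_a, patch_b):
    """Modal face of each planted patch under the winning initialization."""
    import collections

    out = []
    for prepared, struct, patch in ((prediction.prepared_a, struct_a, patch_a),
                                    (prediction.prepared_b, struct_b, patch_b)):
        seg = prepared.inits[prediction.initialization].segmentation
        label_of = {int(i): int(l)
                    for i, l in zip(prepared.surface.surface_atoms, seg.labels)}
        counts = collections.Counter(
            label_of[i] for i in range(len(struct))
            if struct.residue_of(i) in patch and i in label_of)
        out.append(counts.most_common(1)[0][0])
    return tuple(out)


def brute_force_xcorr(a, b):
    """Independent double-loop full cross-correlation oracle."""
    ra, ca = a.shape
    rb, cb = b.shape
    out = np.zeros((ra + rb - 1, ca + cb - 1))
    for k in range(out.shape[0]):
        dr = k - rb + 1
        for l in range(out.shape[1]):
            dc = l - cb + 1
            s = 0.0
            for ib in range(rb):
                ia = ib + dr
                if ia < 0 or ia >= ra:
                    continue
                for jb in range(cb):
                    ja = jb + dc
                    if 0 <= ja < ca:
                        s += a[ia, ja] * b[ib, jb]
            out[k, l] = s
    return out
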