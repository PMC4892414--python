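"""The two-party protocol: flags, guard, concealment, end-to-end search."""

import numpy as np
import pytest

from pbwtsec import (ClientSession, EncQueryVector, HaplotypePanel,
                     ProtocolTranscript, ServerSession, build_concealed_tables,
                     build_pbwt, decode_malicious, guard_w, is_longest,
                     is_longest_gt_eps, lookup_vector, make_rng, ot_reply,
                     prep_query, run_protocol, set_longest_match_plain)
from pbwtsec.crypto import PaillierSecretKey

from conftest import brute_force_longest, random_panel


@pytest.fixture(scope="module")
def panel():
    return HaplotypePanel(np.array([
        [0, 1, 0, 1, 1, 0, 1, 0],
        [0, 1, 0, 1, 0, 0, 1, 1],
        [1, 1, 0, 1, 1, 0, 0, 1],
        [0, 0, 1, 1, 1, 1, 0, 1],
        [1, 0, 0, 1, 1, 0, 1, 0],
    ]))


class TestClientOpen:
    def test_initial_vectors_mark_zero_and_m(self, panel, keypair, rng):
        client = ClientSession([1, 0], 2, [2], panel.M, keypair, 1, rng=rng)
        msg = client.open()
        sk = keypair.secret_key
        f_plain = [sk.decrypt(c) for c in msg.vectors["f"].entries]
        g_plain = [sk.decrypt(c) for c in msg.vectors["g"].entries]
        assert f_plain.index(1) == 0 and g_plain.index(1) == panel.M
        assert msg.n_ciphertexts == 2 * (panel.M + 1) + 1

    def test_decoy_slot_offsets(self, keypair, rng):
        # D=3, true slot x=2, M=4: initial endpoints are o_2=5 and o_2+4=9
        client = ClientSession([1], 7, [3, 7, 11], 4, keypair, 1, rng=rng)
        msg = client.open()
        sk = keypair.secret_key
        f_plain = [sk.decrypt(c) for c in msg.vectors["f"].entries]
        g_plain = [sk.decrypt(c) for c in msg.vectors["g"].entries]
        assert len(f_plain) == 15
        assert f_plain.index(1) == 5 and g_plain.index(1) == 9
        assert msg.n_ciphertexts == 2 * 3 * 5 + 1

    def test_true_position_must_be_declared(self, keypair, rng):
        with pytest.raises(ValueError):
            ClientSession([1], 5, [3, 7], 4, keypair, 1, rng=rng)


class TestConcealedTables:
    def test_single_slot_reduces_to_lookup_vector(self, panel):
        idx = build_pbwt(panel)
        tables = build_concealed_tables(idx, [3], 1)
        for c in range(2):
            assert tables[c] == lookup_vector(idx, 2, c).values.tolist()

    def test_duplicate_positions_shift_by_offset(self, panel):
        idx = build_pbwt(panel)
        tables = build_concealed_tables(idx, [2, 2], 1)
        m1 = panel.M + 1
        for c in range(2):
            first, second = tables[c][:m1], tables[c][m1:]
            assert second == [x + m1 for x in first]

    def test_slots_match_per_column_lookup(self, panel):
        idx = build_pbwt(panel)
        positions = [2, 5, 3]
        for round_i in (1, 2):
            tables = build_concealed_tables(idx, positions, round_i)
            m1 = panel.M + 1
            for c in range(2):
                for j, t_j in enumerate(positions):
                    o_j = j * m1
                    expect = lookup_vector(idx, t_j - 1 + round_i - 1, c).values
                    assert tables[c][o_j : o_j + m1] == [x + o_j for x in expect]

    def test_overflow_raises(self, panel):
        idx = build_pbwt(panel)
        with pytest.raises(ValueError):
            build_concealed_tables(idx, [panel.N], 2)

    def test_final_round_clamps(self, panel):
        idx = build_pbwt(panel)
        tables = build_concealed_tables(idx, [panel.N], 2, n_rounds=2)
        assert set(tables) == {0, 1}


class TestFlags:
    def test_is_longest_zero_iff_equal(self, keypair, rng):
        pk, sk = keypair.public_key, keypair.secret_key
        for f, g in [(3, 3), (0, 6), (2, 4), (5, 5)]:
            qf, qg = prep_query(f, 7, pk, rng), prep_query(g, 7, pk, rng)
            assert sk.is_zero(is_longest(qf, qg, 0, 0, pk, rng)) == (f == g)

    def test_is_longest_with_rotation_offsets(self, keypair, rng):
        pk, sk = keypair.public_key, keypair.secret_key
        f = g = 3
        qf = prep_query((f + 2) % 7, 7, pk, rng)
        qg = prep_query((g + 5) % 7, 7, pk, rng)
        assert sk.is_zero(is_longest(qf, qg, 2, 5, pk, rng))

    def test_fresh_randomness_same_verdict(self, keypair, rng):
        pk, sk = keypair.public_key, keypair.secret_key
        qf, qg = prep_query(1, 5, pk, rng), prep_query(4, 5, pk, rng)
        d1 = is_longest(qf, qg, 0, 0, pk, rng)
        d2 = is_longest(qf, qg, 0, 0, pk, rng)
        assert d1.value != d2.value
        assert not sk.is_zero(d1) and not sk.is_zero(d2)

    def test_eps_one_matches_is_longest(self, keypair, rng):
        pk, sk = keypair.public_key, keypair.secret_key
        for f, g in [(2, 2), (1, 4)]:
            qf, qg = prep_query(f, 6, pk, rng), prep_query(g, 6, pk, rng)
            flags = is_longest_gt_eps(qf, qg, 0, 0, 1, pk, rng)
            assert len(flags) == 1
            assert sk.is_zero(flags[0]) == \
                sk.is_zero(is_longest(qf, qg, 0, 0, pk, rng))

    @pytest.mark.parametrize("f,g,eps,expect_zero", [
        (2, 4, 3, True),   # g - f = 2 < eps
        (2, 5, 3, False),  # g - f = eps exactly
        (3, 3, 2, True),
        (0, 6, 2, False),
    ])
    def test_gt_eps_threshold(self, keypair, rng, f, g, eps, expect_zero):
        pk, sk = keypair.public_key, keypair.secret_key
        qf, qg = prep_query(f, 7, pk, rng), prep_query(g, 7, pk, rng)
        flags = is_longest_gt_eps(qf, qg, 0, 0, eps, pk, rng)
        assert len(flags) == eps
        assert any(sk.is_zero(fl) for fl in flags) == expect_zero


class TestGuardAndAttack:
    def craft_two_slot(self, pk, rng, i, j, x, length):
        entries = []
        for pos in range(length):
            m = 1 if pos == i else (x if pos == j else 0)
            entries.append(pk.encrypt(m, rng))
        return EncQueryVector(tuple(entries))

    def test_guard_zero_for_unit_vectors(self, keypair, rng):
        pk, sk = keypair.public_key, keypair.secret_key
        for t in range(4):
            assert sk.is_zero(guard_w(prep_query(t, 4, pk, rng), pk, rng))

    def test_guard_nonzero_for_malformed_sums(self, keypair, rng):
        pk, sk = keypair.public_key, keypair.secret_key
        zeros = EncQueryVector(tuple(pk.encrypt(0, rng) for _ in range(4)))
        two_ones = EncQueryVector(
            tuple(pk.encrypt(int(i < 2), rng) for i in range(4)))
        assert not sk.is_zero(guard_w(zeros, pk, rng))
        assert not sk.is_zero(guard_w(two_ones, pk, rng))

    def test_worked_example_decode(self):
        decoded = decode_malicious(821, 100)
        assert decoded.mod_part == 21 and decoded.div_part == 8

    def test_decode_zero_aggregate(self):
        assert tuple(decode_malicious(0, 100)) == (0, 0)

    def test_decode_rejects_bad_multiplier(self):
        with pytest.raises(ValueError):
            decode_malicious(821, 0)

    def test_attack_succeeds_without_guard(self, keypair, rng):
        pk, sk = keypair.public_key, keypair.secret_key
        v = [21, 8, 13, 4]
        q = self.craft_two_slot(pk, rng, 0, 1, 100, 4)
        agg = sk.decrypt(ot_reply(q, v, pk, rng))
        decoded = decode_malicious(agg, 100)
        assert decoded.mod_part == v[0] and decoded.div_part == v[1]

    def test_attack_blocked_with_guard(self, keypair, rng):
        pk, sk = keypair.public_key, keypair.secret_key
        v = [21, 8, 13, 4]
        q = self.craft_two_slot(pk, rng, 0, 1, 100, 4)
        truth = v[0] + 100 * v[1]
        guarded = pk.add(ot_reply(q, v, pk, rng), guard_w(q, pk, rng))
        assert sk.decrypt(guarded) != truth


class TestServerRound:
    def test_zero_masks_expose_interval_update(self, panel, keypair, rng):
        """With the test hook zeroing every server mask, decrypting the
        reply for the true letter gives exactly the lookup-table update."""
        idx = build_pbwt(panel)
        t, letter = 3, 1
        client = ClientSession([letter], t, [t], panel.M, keypair, 1,
                               rng=rng)
        server = ServerSession(idx, keypair.public_key, [t], 1, 2,
                               zero_masks=True, guard=False, rng=rng)
        reply = server.round(client.open())
        sk = keypair.secret_key
        v = lookup_vector(idx, t - 1, letter).values
        assert sk.decrypt(reply.e_f[letter]) == v[0]
        assert sk.decrypt(reply.e_g[letter]) == v[panel.M]

    def test_wrong_letter_replies_randomized(self, panel, keypair, rng):
        idx = build_pbwt(panel)
        t, letter = 3, 1
        client = ClientSession([letter], t, [t], panel.M, keypair, 1, rng=rng)
        server = ServerSession(idx, keypair.public_key, [t], 1, 2, rng=rng)
        reply = server.round(client.open())
        sk = keypair.secret_key
        wrong = 1 - letter
        v = lookup_vector(idx, t - 1, wrong).values
        assert sk.decrypt(reply.e_f[wrong]) != v[0]
        assert sk.decrypt(reply.e_g[wrong]) != v[panel.M]

    def test_reply_counts_binary_alphabet(self, panel, keypair, rng):
        idx = build_pbwt(panel)
        client = ClientSession([1, 0], 3, [3], panel.M, keypair, 2, rng=rng)
        server = ServerSession(idx, keypair.public_key, [3], 2, 3, rng=rng)
        reply = server.round(client.open())
        assert reply.n_ciphertexts == 2 * 2 + 2  # 4 interval cts + eps flags


def _contains_secret_key(obj, seen=None, depth=0) -> bool:
    if seen is None:
        seen = set()
    if id(obj) in seen or depth > 6:
        return False
    seen.add(id(obj))
    if isinstance(obj, PaillierSecretKey):
        return True
    children = []
    if hasattr(obj, "__dict__"):
        children.extend(vars(obj).values())
    if isinstance(obj, dict):
        children.extend(obj.values())
    elif isinstance(obj, (list, tuple, set)):
        children.extend(obj)
    return any(_contains_secret_key(ch, seen, depth + 1) for ch in children)


class TestEndToEnd:
    def test_planted_prefix_full_match(self, panel, keypair):
        q = panel.sequences[2, 1:5]
        res = run_protocol(panel, q, 2, keypair=keypair, seed=0)
        assert res.match_length == 4

    @pytest.mark.parametrize("transport", ["linear", "scot"])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_plaintext_oracle(self, keypair, transport, seed):
        np_rng = np.random.default_rng(500 + seed)
        panel = random_panel(np_rng, m_max=10, n_max=25)
        ell = int(np_rng.integers(1, 8))
        t = int(np_rng.integers(1, panel.N - ell + 2))
        q = np_rng.integers(0, 2, size=ell)
        d = 1 + 2 * (seed % 2)
        eps = 1 + (seed % 2)
        res = run_protocol(panel, q, t, D=d, eps=eps, keypair=keypair,
                           seed=seed, transport=transport)
        expect, _ = brute_force_longest(panel, q, t, eps)
        assert res.match_length == expect

    def test_round_count_constant_even_for_instant_mismatch(self, keypair):
        # first query letter absent from the panel: match ends at round 2,
        # but the transcript still spans the full ell + 1 rounds of decoys
        panel = HaplotypePanel(np.zeros((3, 10), dtype=int))
        q = [1, 0, 1, 1, 0]
        res = run_protocol(panel, q, 2, keypair=keypair, seed=1)
        assert res.match_length == 0
        assert res.transcript.rounds == len(q) + 1

    def test_shape_indistinguishability(self, panel, keypair):
        """Fixed public parameters: per-round counts are identical whatever
        the query content and wherever the match ends."""
        shapes = []
        for seed, q in [(1, [1, 1, 1, 1]), (2, [0, 1, 0, 1]),
                        (3, list(panel.sequences[0, 2:6]))]:
            res = run_protocol(panel, q, 3, D=2, eps=2, keypair=keypair,
                               seed=seed)
            shapes.append((res.transcript.uploads_per_round(),
                           res.transcript.downloads_per_round()))
        assert shapes[0] == shapes[1] == shapes[2]
        ups, downs = shapes[0]
        assert len(set(ups)) == 1 and len(set(downs)) == 1

    def test_server_state_never_references_secret_key(self, panel, keypair, rng):
        idx = build_pbwt(panel)
        server = ServerSession(idx, keypair.public_key, [3], 1, 3, rng=rng)
        client = ClientSession([1, 0], 3, [3], panel.M, keypair, 1, rng=rng)
        msg = client.open()
        while msg is not None:
            msg = client.consume(server.round(msg))
        assert not _contains_secret_key(server)
        assert _contains_secret_key(client)  # sanity: the walker does find keys

    def test_guard_active_by_default_preserves_honest_runs(self, panel, keypair):
        q = panel.sequences[0, 0:3]
        res = run_protocol(panel, q, 1, keypair=keypair, seed=4, guard=True)
        expect, _ = set_longest_match_plain(build_pbwt(panel), q, 1)
        assert res.match_length == expect

    def test_eps_out_of_range_rejected(self, panel, keypair):
        with pytest.raises(ValueError):
            run_protocol(panel, [0, 1], 1, eps=panel.M + 1, keypair=keypair, seed=0)
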