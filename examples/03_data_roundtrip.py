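"""Encrypt a text end-to-end into a shuffled DNA mixture and decrypt it back.

One session draws every secret (logistic pairs, three encoding rules, table
iteration Pk, adapter + indexes).  The plaintext becomes a DNA ciphertext
(XOR with the chaotic keystream, 512x512 Arnold bit scrambling, 2 bits/nt),
is cut into 160-nt payloads flanked by 20-nt reassembly regions, and ships
as an anonymized, shuffled multi-FASTA.  The receiver needs the session
file (channel secret) plus the two amino-acid ciphertexts C0/C1.
"""

from dnaotp import session as S

plaintext = "Store me as molecules, please — but keep the key chaotic."
plaintext = plaintext.replace("—", "-")  # ASCII payloads only

sess = S.new_session(seed=2024)
msg = S.encrypt_message(plaintext, sess)

n_records = msg.mixture_fasta.count(">")
print(f"C0 (security params, {len(msg.c0)} aa) : {msg.c0}")
print(f"C1 (confounding,   {len(msg.c1)} aa)  : {msg.c1}")
print(f"mixture: {n_records} sequencing structures of 200 nt each")
print(f"recorded plaintext bits: {sess.data.bit_length}")

recovered = S.decrypt_message(msg.c0, msg.c1, msg.mixture_fasta, sess)
print("round trip exact:", recovered == plaintext)
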