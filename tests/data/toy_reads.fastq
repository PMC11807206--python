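@r1
TTTTAAAAAAAAACGTACGT
+
IIIIIIIIIIIIIIIIIIII
@r2
TTTTAAAAAAAAACGTACGT
+
IIIIIIIIIIIIIIIIIIII
@r3
TTTTCCCCCCCCACGTACGT
+
IIIIIIIIIIIIIIIIIIII
@r4
TTTTAAAAAAACACGTACGT
+
IIIIIIIIIIIIIIIIIIII
@r5
TTTTGGGGGGTTACGTACGT
+
IIIIIIIIIIIIIIIIIIII
@r6
TTTTACGTACGTACGTACGT
+
IIIIIIIIIIIIIIIIIIII
@r7
TTTTGGGGGGGGACGTACGT
+
IIIIIIIIIIIIIIIIIIII
@r8
TTTTCCCCCCCCACGTACGT
+
IIIIIIIIIIIIIIIIIIII
@r9
TTTTCCCCCCACACGTACGT
+
IIIIIIIIIIIIIIIIIIII
@r10
TTTTAA
+
IIIIII
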