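# toy function-word stoplist
the
a
an
of
to
in
and
or
is
was
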