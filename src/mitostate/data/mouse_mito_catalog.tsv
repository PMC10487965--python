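symbol	biotype	chromosome
mt-Nd1	mRNA	MT
mt-Nd2	mRNA	MT
mt-Co1	mRNA	MT
mt-Co2	mRNA	MT
mt-Atp8	mRNA	MT
mt-Atp6	mRNA	MT
mt-Co3	mRNA	MT
mt-Nd3	mRNA	MT
mt-Nd4l	mRNA	MT
mt-Nd4	mRNA	MT
mt-Nd5	mRNA	MT
mt-Nd6	mRNA	MT
mt-Cytb	mRNA	MT
mt-Rnr1	rRNA	MT
mt-Rnr2	rRNA	MT
mt-Tf	tRNA	MT
mt-Tv	tRNA	MT
mt-Tl1	tRNA	MT
mt-Ti	tRNA	MT
mt-Tq	tRNA	MT
mt-Tm	tRNA	MT
mt-Tw	tRNA	MT
mt-Ta	tRNA	MT
mt-Tn	tRNA	MT
mt-Tc	tRNA	MT
mt-Ty	tRNA	MT
mt-Ts1	tRNA	MT
mt-Td	tRNA	MT
mt-Tk	tRNA	MT
mt-Tg	tRNA	MT
mt-Tr	tRNA	MT
mt-Th	tRNA	MT
mt-Ts2	tRNA	MT
mt-Tl2	tRNA	MT
mt-Te	tRNA	MT
mt-Tt	tRNA	MT
mt-Tp	tRNA	MT
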