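satellite	species	chromosome	pattern	regions
ApaSat01-51	A. fasciatus	BfMa	c	q:i
ApaSat01-51	A. bockmanni	BbM	c	p:t;q:t
ApaSat02-236	A. paranae	BpM	c	pe
ApaSat02-236	A. fasciatus	BfMa	c	pe
ApaSat04-233	A. fasciatus	BfMa	c	pe
ApaSat04-233	A. bockmanni	BbM	c	pe
ApaSat05-23	A. paranae	BpM	c	p:t;q:t
ApaSat05-23	A. fasciatus	BfMa	c	p:t
ApaSat06-86	A. paranae	BpM	c	pe;p:i;p:t;q:i;q:t
ApaSat06-86	A. fasciatus	BfMa	c	pe;p:i;q:i
ApaSat06-86	A. bockmanni	BbM	c	p:t;q:t
ApaSat07-6-tel	A. paranae	BpM	t	p:t;q:t
ApaSat07-6-tel	A. fasciatus	BfMa	t	p:t;q:t
ApaSat07-6-tel	A. bockmanni	BbM	t	p:t;q:t
ApaSat08-35	A. paranae	BpM	c	p:t;q:t
ApaSat13-22	A. fasciatus	BfMa	c	p:t
ApaSat13-22	A. bockmanni	BbM	c	p:t;q:t
ApaSat14-184	A. paranae	BpM	c	p:t;q:t
ApaSat14-184	A. fasciatus	BfMa	c	p:t;q:d
ApaSat14-184	A. bockmanni	BbM	c	p:t;q:t
ApaSat15-51	A. paranae	BpM	c	p:t;q:t
ApaSat17-365	A. fasciatus	BfMa	c	p:i;p:t;q:i;q:t
ApaSat18-58	A. paranae	BpM	c	p:i;q:i
ApaSat18-58	A. fasciatus	BfMa	c	pe;p:i;q:i
ApaSat19-77	A. paranae	BpM	c	p:i;q:i
ApaSat19-77	A. fasciatus	BfMa	c	q:i
ApaSat19-77	A. bockmanni	BbM	c	p:t;q:t
ApaSat20-18	A. paranae	BpM	c	p:t;q:t
ApaSat20-18	A. fasciatus	BfMa	c	q:i
ApaSat20-18	A. bockmanni	BbM	c	p:i;p:t;q:i;q:t
ApaSat33-112	A. paranae	BpM	c	p:t;q:t
ApaSat33-112	A. fasciatus	BfMa	c	p:i;q:i
ApaSat33-112	A. bockmanni	BbM	c	p:i;p:t;q:i;q:t
ApaSat34-59	A. paranae	BpM	c	p:t;q:t
ApaSat40-189	A. paranae	BpM	c	pe;p:i;p:t;q:i;q:t
ApaSat42-90	A. paranae	BpM	c	p:i;p:t;q:i;q:t
ApaSat42-90	A. fasciatus	BfMa	c	p:i
ApaSat44-21	A. paranae	BpM	c	pe;p:i;q:i
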