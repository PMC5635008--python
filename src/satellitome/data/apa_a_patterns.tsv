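satellite	A. paranae	A. fasciatus	A. bockmanni
ApaSat01-51	c	c	c
ApaSat02-236	c	c	c
ApaSat03-91	c	c	c
ApaSat04-233	c	c	c
ApaSat05-23	c	-	c
ApaSat06-86	c	c	c
ApaSat07-6-tel	t	t	t
ApaSat08-35	c	c	-
ApaSat13-22	c	c	c
ApaSat14-184	c	c	c
ApaSat15-51	c	c	c
ApaSat17-365	c	c	c
ApaSat18-58	c	c	c
ApaSat19-77	c	c	c
ApaSat20-18	nc	c	c
ApaSat22-63	c	-	-
ApaSat23-37	c	c	c
ApaSat24-78	c	c	c
ApaSat26-195	c	-	c
ApaSat27-178	c	-	c
ApaSat28-52	c	c	c
ApaSat30-50	c	c	c
ApaSat31-165	c	-	c
ApaSat32-85	c	-	c
ApaSat33-112	c	c	c
ApaSat34-59	c	c	-
ApaSat35-37	c	-	-
ApaSat36-21	nc	-	c
ApaSat37-38	nc	-	-
ApaSat38-107	nc	-	-
ApaSat39-32	c	-	c
ApaSat40-189	c	-	-
ApaSat42-90	c	-	-
ApaSat43-61	c	c	c
ApaSat44-21	nc	-	-
ApaSat45-113	c	-	c
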