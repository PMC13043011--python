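# function-word stoplist for content-word proportion
a
an
the
and
or
but
if
then
than
so
as
of
at
by
for
with
about
against
between
into
through
during
before
after
above
below
to
from
up
down
in
out
on
off
over
under
again
further
once
here
there
when
where
why
how
all
any
both
each
few
more
most
other
some
such
only
own
same
very
can
will
just
should
now
i
me
my
myself
we
our
ours
you
your
yours
he
him
his
she
her
hers
it
its
they
them
their
what
which
who
whom
this
that
these
those
am
is
are
was
were
be
been
being
have
has
had
having
do
does
did
doing
would
could
ought
im
ive
id
youre
hes
shes
its
were
theyre
dont
didnt
wont
isnt
arent
wasnt
werent
i'm
i've
i'd
you're
he's
she's
they're
don't
didn't
won't
isn't
aren't
wasn't
weren't
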